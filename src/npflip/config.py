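"""Strictly parsed YAML configuration with a named default for every knob.

Sections mirror the pipeline stages: ``geometry`` (NP and bilayer
construction), ``physics`` (solvation, probe, bias parameters),
``analysis`` (cutoffs, bins, generator statistics) and ``landscape``
(published component estimates).  Unknown keys are rejected outright —
a misspelled parameter must never be silently ignored.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .core import Role
from .errors import ConfigurationError
from .landscape import LandscapeDefaults
from .sasa import SasaParams
from .synthetic import GeneratorParams

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    core_diameter: float = 2.0
    n_ligands: int = 58
    mus_fraction: float = 0.5
    n_core_beads: int = 92
    n_lipids: int = 334
    area_per_lipid: float = 0.65
    head_offset: float = 1.9


class PhysicsSection(_Strict):
    gamma: float = 4.7                 # kcal/mol/nm^2, water -> alkane
    probe_radius: float = 0.14         # nm
    n_sphere_points: int = 960
    spring_constant: float = 3000.0    # kJ/mol/nm^2, as printed for pull codes
    pull_duration: float = 1.5         # ns
    equilibration: float = 20.0        # ns
    salt_conc: float = 0.150           # M
    n_water: int = 21418
    n_cl_override: Optional[int] = 60
    vdw_radii: dict[str, float] = {}   # role-name keyed overrides, nm


class AnalysisSection(_Strict):
    contact_threshold: float = 0.7     # nm, sulfonate S - choline N
    polar_thresholds: dict[str, float] = {}
    rdf_dr: float = 0.02
    rdf_r_max: float = 1.5
    smooth_window: int = 3
    n_frames: int = 10
    noise_sigma: float = 0.05
    hydration_slope: float = 4.0
    hydration_floor: float = 2.0
    depth_max: float = 1.0


class LandscapeSection(_Strict):
    protrusion_dg: float = 6.0
    two_state_reference_dg: float = -232.1
    two_state_reference_err: float = 5.6
    per_leaflet_insertion_dg: float = -115.05
    per_leaflet_insertion_err: float = 2.8
    reference_n_ligands: int = 65
    target_n_ligands: int = 58
    flip_barrier: float = 11.2
    flip_barrier_err: float = 0.2
    per_flip_drive_mean: float = -3.6
    per_flip_drive_err: float = 0.4
    per_flip_drive_min: float = 0.0
    per_flip_drive_max: float = -17.3
    iterative_flipping_dg: float = -52.1
    iterative_flipping_err: float = 2.9
    n_flips: int = 14


class RunConfig(_Strict):
    seed: int = 0
    outdir: Optional[str] = None
    geometry: GeometrySection = GeometrySection()
    physics: PhysicsSection = PhysicsSection()
    analysis: AnalysisSection = AnalysisSection()
    landscape: LandscapeSection = LandscapeSection()

    # --- adapters into the library's parameter objects -------------------
    def generator_params(self, n_plus: int | None = None,
                         n_minus: int | None = None,
                         n_frames: int | None = None) -> GeneratorParams:
        g, a = self.geometry, self.analysis
        n_mus = round(g.n_ligands * g.mus_fraction)
        if n_plus is None:
            n_plus = n_mus if n_minus is None else n_mus - n_minus
        if n_minus is None:
            n_minus = n_mus - n_plus
        return GeneratorParams(
            n_plus=n_plus, n_minus=n_minus, depth_max=a.depth_max,
            noise_sigma=a.noise_sigma, hydration_slope=a.hydration_slope,
            hydration_floor=a.hydration_floor,
            n_frames=n_frames if n_frames is not None else a.n_frames,
            seed=self.seed, core_diameter=g.core_diameter,
            n_ligands=g.n_ligands, mus_fraction=g.mus_fraction,
            n_lipids=g.n_lipids, area_per_lipid=g.area_per_lipid,
            head_offset=g.head_offset, n_water_total=self.physics.n_water,
            salt_conc=self.physics.salt_conc,
            n_cl_override=self.physics.n_cl_override,
        )

    def sasa_params(self) -> SasaParams:
        from .core import DEFAULT_VDW_RADII

        table = dict(DEFAULT_VDW_RADII)
        for name, radius in self.physics.vdw_radii.items():
            if name not in Role.__members__:
                raise ConfigurationError(f"vdw_radii: unknown role {name!r}")
            table[Role[name]] = radius
        return SasaParams(probe_radius=self.physics.probe_radius,
                          n_sphere_points=self.physics.n_sphere_points,
                          radii_table=table)

    def polar_thresholds(self) -> dict[Role, float]:
        from .analysis import DEFAULT_POLAR_THRESHOLDS

        table = dict(DEFAULT_POLAR_THRESHOLDS)
        for name, value in self.analysis.polar_thresholds.items():
            if name not in Role.__members__:
                raise ConfigurationError(
                    f"polar_thresholds: unknown role {name!r}")
            table[Role[name]] = value
        return table

    def landscape_defaults(self) -> LandscapeDefaults:
        return LandscapeDefaults(**self.landscape.model_dump())


def load_config(path) -> RunConfig:
    """Parse a YAML config; unknown or misspelled keys raise."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
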