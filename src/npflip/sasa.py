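"""Solvent-accessible surface area by Shrake-Rupley sphere quadrature.

Each atom is inflated by the probe radius (0.14 nm by default, a water
probe) and covered with a deterministic golden-section spiral of test
points; the accessible fraction is the share of points not buried inside
any neighbor's inflated sphere.  Restricting the subset to the ligand
backbone carbons gives the nonpolar SASA whose decrease upon ligand
flipping drives insertion; the hydrophobic free energy follows the linear
solvation model dG = gamma * dSASA with gamma = 4.7 kcal/mol/nm^2 for a
water-to-alkane transfer.

Waters and ions define the solvent and therefore never occlude; all other
atoms in the frame do, whether or not they are in the measured subset.
Quadrature error is controlled by ``n_sphere_points`` and is testable
against closed-form sphere and two-sphere areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    DEFAULT_VDW_RADII,
    Frame,
    NPModel,
    Role,
    SOLVENT_ROLES,
    fibonacci_sphere,
)
from .errors import ConfigurationError, TopologyMismatchError

__all__ = [
    "SasaParams",
    "SasaResult",
    "HydrophobicEnergy",
    "GAMMA_WATER_ALKANE",
    "shrake_rupley",
    "nonpolar_subset",
    "nonpolar_subset_from_roles",
    "delta_sasa",
    "hydrophobic_dg",
]

#: Water-to-alkane transfer solvation parameter, kcal/mol/nm^2.
GAMMA_WATER_ALKANE = 4.7


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 0.14
    n_sphere_points: int = 960
    radii_table: Mapping[Role, float] = field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII))
    solvent_roles: frozenset = SOLVENT_ROLES

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ConfigurationError("probe_radius must be >= 0")
        if self.n_sphere_points < 32:
            raise ConfigurationError("n_sphere_points must be >= 32")


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and total accessible area (nm^2) over a named subset."""

    atom_indices: np.ndarray
    per_atom_area: np.ndarray
    subset_descriptor: str = ""

    def __post_init__(self):
        if (np.asarray(self.per_atom_area) < 0).any():
            raise ValueError("areas must be >= 0")

    @property
    def total_area(self) -> float:
        return float(np.sum(self.per_atom_area))


@dataclass(frozen=True)
class HydrophobicEnergy:
    """Linear hydrophobic solvation energy: dg = gamma * delta_sasa."""

    gamma: float
    delta_sasa: float

    @property
    def dg(self) -> float:
        return self.gamma * self.delta_sasa


def _expanded_radii(frame: Frame, params: SasaParams) -> np.ndarray:
    table = params.radii_table
    try:
        radii = np.array([table[Role(r)] for r in frame.roles])
    except KeyError as exc:
        raise ConfigurationError(
            f"radii_table has no entry for role {Role(exc.args[0]).name}"
        ) from exc
    return radii + params.probe_radius


def shrake_rupley(frame: Frame, subset: Sequence[int],
                  params: SasaParams | None = None,
                  subset_descriptor: str = "") -> SasaResult:
    """SASA of ``subset`` atoms with every non-solvent atom as an occluder.

    Boxes are treated as non-periodic here: the systems this package builds
    keep the NP far from the box walls, so image occlusion is negligible.
    """
    params = params or SasaParams()
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ConfigurationError("subset must be nonempty")
    r_exp = _expanded_radii(frame, params)

    occluder_idx = np.flatnonzero(
        ~np.isin(frame.roles, [int(r) for r in params.solvent_roles]))
    occ_pos = frame.positions[occluder_idx]
    occ_r = r_exp[occluder_idx]
    tree = cKDTree(occ_pos) if len(occ_pos) else None
    max_occ_r = occ_r.max() if len(occ_r) else 0.0

    unit_points = fibonacci_sphere(params.n_sphere_points)
    areas = np.empty(subset.size)
    for k, i in enumerate(subset):
        ri = r_exp[i]
        center = frame.positions[i]
        if tree is not None:
            nb = tree.query_ball_point(center, ri + max_occ_r)
            nb = np.asarray(nb, dtype=int)
            nb_global = occluder_idx[nb]
            keep = nb_global != i
            d = np.linalg.norm(occ_pos[nb] - center, axis=1)
            keep &= d < ri + occ_r[nb]
            nb = nb[keep]
        else:
            nb = np.array([], dtype=int)
        pts = center + ri * unit_points
        if nb.size:
            d2 = ((pts[:, None, :] - occ_pos[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 < occ_r[nb][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[k] = frac * 4.0 * math.pi * ri * ri
    return SasaResult(subset, areas, subset_descriptor)


def nonpolar_subset(np_model: NPModel) -> np.ndarray:
    """Frame indices of all ligand backbone carbons (MUS and OT).

    Excludes the sulfonate S/O, thiol anchors, and the gold core: the
    quantity of interest is the *nonpolar* ligand surface.
    """
    idx: list[int] = []
    for lig in np_model.ligands:
        idx.extend(lig.backbone_atoms)
    return np.array(sorted(idx), dtype=int)


def nonpolar_subset_from_roles(frame: Frame) -> np.ndarray:
    """Role-based fallback when no NP topology accompanies a frame."""
    return np.flatnonzero(frame.mask(Role.LIGAND_C_MUS, Role.LIGAND_C_OT))


def delta_sasa(frame: Frame, reference: Frame, np_model: NPModel,
               params: SasaParams | None = None) -> float:
    """Nonpolar-subset SASA of ``frame`` minus that of ``reference`` (nm^2).

    Both frames must share the NP topology (same subset indices and roles);
    in the published analysis the reference is the 29+/0- configuration.
    """
    subset = nonpolar_subset(np_model)
    for f in (frame, reference):
        if subset.size and (subset.max() >= f.n_atoms or not np.array_equal(
                f.roles[subset], frame.roles[subset])):
            raise TopologyMismatchError(
                "frames do not share the NP ligand topology")
    a = shrake_rupley(frame, subset, params, "nonpolar").total_area
    b = shrake_rupley(reference, subset, params, "nonpolar").total_area
    return a - b


def hydrophobic_dg(delta_sasa_nm2: float,
                   gamma: float = GAMMA_WATER_ALKANE) -> HydrophobicEnergy:
    """Hydrophobic free-energy change for a SASA change (kcal/mol).

    A SASA decrease (negative input) gives a negative, favorable dG.
    """
    if not math.isfinite(gamma):
        raise ConfigurationError("gamma must be finite")
    return HydrophobicEnergy(gamma, delta_sasa_nm2)
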