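"""Synthetic NP-bilayer configurations with the statistics the analyses assume.

Real input to the analyses would be equilibrated MD configurations; this
module generates stand-ins that reproduce their *statistical* structure —
not their chemistry — so the whole pipeline can run end to end:

* a target charged-ligand distribution n+/m- (which end groups sit above
  vs below the midplane), recoverable by the classifier;
* an NP core height above the midplane that decreases linearly with the
  number of flipped ligands (``depth_max * (half - n_minus) / half``);
* an end-group hydration gradient: each sulfonate carries a water shell of
  ``hydration_floor + hydration_slope * |d_z|`` molecules, so coordination
  numbers grow with distance from the midplane.

Layout choices serve measurability: end groups occupy a laterally spaced
grid around the NP axis and lipids are kept outside that region, so each
end group's coordination counts only its own shell.  Geometry is otherwise
schematic; see docs/methods.md for what this does and does not emulate.
All randomness is truncated-Gaussian jitter on deterministic placements,
streamed per (seed, frame_index): identical inputs give identical bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import (
    Frame,
    LigandKind,
    NPModel,
    Role,
    build_bilayer,
    build_np,
    ion_counts,
    midplane_z,
    sulfonate_atoms,
)
from .errors import CompositionError, FlipError

__all__ = [
    "GeneratorParams",
    "gen_frame",
    "gen_trajectory",
    "flip_ligand_synthetic",
    "resample_frames",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic system; defaults mirror the published setup.

    ``n_plus``/``n_minus`` partition the charged (MUS) end groups above and
    below the midplane and must sum to the NP's MUS count (29 by default).
    ``depth_max`` is the core height above the midplane in the unflipped
    29+/0- state (nm); ``hydration_floor``/``hydration_slope`` set the
    water-shell law (molecules, molecules per nm of |d_z|).
    """

    n_plus: int = 29
    n_minus: int = 0
    depth_max: float = 1.0
    noise_sigma: float = 0.05
    hydration_slope: float = 4.0
    hydration_floor: float = 2.0
    n_frames: int = 1
    seed: int = 0
    # NP / bilayer construction
    core_diameter: float = 2.0
    n_ligands: int = 58
    mus_fraction: float = 0.5
    n_lipids: int = 334
    area_per_lipid: float = 0.65
    head_offset: float = 1.9
    # end-group layout and hydration shells
    water_threshold: float = 0.7
    shell_radius_fraction: float = 0.45
    slot_spacing: float = 1.4
    lipid_gap_margin: float = 1.0
    dz_min_fraction: float = 0.1
    # solvent/ion bookkeeping (waters beyond the shells are implicit)
    n_water_total: int = 21418
    salt_conc: float = 0.150
    n_cl_override: int | None = 60
    frame_spacing_ns: float = 1.0

    def __post_init__(self):
        n_mus = round(self.n_ligands * self.mus_fraction)
        if self.n_plus < 0 or self.n_minus < 0:
            raise CompositionError("n_plus and n_minus must be >= 0")
        if self.n_plus + self.n_minus != n_mus:
            raise CompositionError(
                f"n_plus + n_minus must equal the MUS count ({n_mus})"
            )
        if self.noise_sigma < 0:
            raise CompositionError("noise_sigma must be >= 0")
        if self.hydration_slope < 0 or self.hydration_floor < 0:
            raise CompositionError("hydration law parameters must be >= 0")
        if self.n_frames < 1:
            raise CompositionError("n_frames must be >= 1")

    @property
    def n_mus(self) -> int:
        return round(self.n_ligands * self.mus_fraction)

    @property
    def shell_radius(self) -> float:
        return self.shell_radius_fraction * self.water_threshold


def _jitter(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    """Gaussian jitter truncated at 3 sigma (clipped)."""
    if sigma == 0:
        return np.zeros(shape)
    return sigma * np.clip(rng.standard_normal(shape), -3.0, 3.0)


def _slots(n: int, spacing: float) -> np.ndarray:
    """n lateral grid sites (xy, nm) around the axis, compact and deterministic."""
    if n == 0:
        return np.zeros((0, 2))
    m = int(math.ceil(math.sqrt(n))) + 2
    pts = [(i * spacing, j * spacing)
           for i in range(-m, m + 1) for j in range(-m, m + 1)]
    pts.sort(key=lambda p: (round(p[0] ** 2 + p[1] ** 2, 9),
                            math.atan2(p[1], p[0])))
    return np.array(pts[:n])


def _dz_targets(params: GeneratorParams) -> np.ndarray:
    """Per-MUS-ligand |d_z| placement targets, frame-independent."""
    rng = np.random.default_rng([params.seed, 9001])
    return rng.uniform(params.dz_min_fraction, 1.0,
                       params.n_mus) * params.head_offset


def _shell_count(params: GeneratorParams, abs_dz: float) -> int:
    return int(round(params.hydration_floor
                     + params.hydration_slope * abs_dz))


def _shell_waters(rng: np.random.Generator, center: np.ndarray,
                  radius: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 3))
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v


def gen_frame(params: GeneratorParams, frame_index: int = 0) -> Frame:
    """One synthetic configuration at the requested ligand distribution.

    Atom order is fixed: NP atoms first (so the embedded ``NPModel`` indices
    are frame indices), then lipids, ions, and finally the hydration-shell
    waters in ligand order.  Deterministic given (params.seed, frame_index).
    """
    rng = np.random.default_rng([params.seed, 101, frame_index])
    npm = build_np(params.core_diameter, params.n_ligands,
                   params.mus_fraction, params.seed)
    mus_ids = npm.mus_ligand_ids()
    half = max(npm.n_mus // 2, 1)

    dz_mag = _dz_targets(params)
    signs = {lid: (1.0 if k < params.n_plus else -1.0)
             for k, lid in enumerate(mus_ids)}
    slots = _slots(npm.n_mus, params.slot_spacing)
    grid_r = float(np.hypot(slots[:, 0], slots[:, 1]).max()) if len(slots) else 0.0
    exclusion = grid_r + params.lipid_gap_margin

    core_h = params.depth_max * (half - params.n_minus) / half
    core_h += float(_jitter(rng, params.noise_sigma, ()))

    bilayer = build_bilayer(
        params.n_lipids, params.area_per_lipid,
        npm.translated([0.0, 0.0, core_h]),
        head_offset=params.head_offset, exclusion_radius=exclusion,
    )
    center = bilayer.box / 2.0

    # NP embedded at (center_x, center_y, midplane + core height), jittered.
    np_pos = npm.positions + center + [0.0, 0.0, core_h]
    np_pos = np_pos + _jitter(rng, params.noise_sigma, np_pos.shape)

    # Charged end groups overridden onto their lateral slots and dz targets.
    for k, lid in enumerate(mus_ids):
        lig = npm.ligands[lid]
        s = signs[lid]
        s_pos = np.array([center[0] + slots[k, 0], center[1] + slots[k, 1],
                          center[2] + s * dz_mag[k]])
        group = sulfonate_atoms(s_pos, np.array([0.0, 0.0, s]))
        group += _jitter(rng, params.noise_sigma, group.shape)
        np_pos[lig.endgroup_atoms] = group

    positions = [np_pos]
    roles = [npm.roles]

    lip_pos = bilayer.positions + _jitter(rng, params.noise_sigma,
                                          bilayer.positions.shape)
    positions.append(lip_pos)
    roles.append(bilayer.roles)

    # Static placements (ions, shell directions) come from a
    # frame-independent stream so noise_sigma = 0 means identical frames.
    rng_static = np.random.default_rng([params.seed, 4242])
    n_na, n_cl = ion_counts(params.n_water_total, npm.net_charge,
                            params.salt_conc, params.n_cl_override)
    ion_z_lo = params.head_offset + params.lipid_gap_margin
    ion_z_hi = bilayer.box[2] / 2.0 - 0.2
    ion_pos = np.column_stack([
        rng_static.uniform(0, bilayer.box[0], n_na + n_cl),
        rng_static.uniform(0, bilayer.box[1], n_na + n_cl),
        center[2] + rng_static.choice([-1.0, 1.0], n_na + n_cl)
        * rng_static.uniform(ion_z_lo, ion_z_hi, n_na + n_cl),
    ])
    ion_pos = ion_pos + _jitter(rng, params.noise_sigma, ion_pos.shape)
    positions.append(ion_pos)
    roles.append(np.array([int(Role.ION_NA)] * n_na
                          + [int(Role.ION_CL)] * n_cl, int))

    n_before = len(np_pos) + len(lip_pos) + len(ion_pos)
    shells: list[tuple[int, int, int]] = []
    water_blocks = []
    cursor = n_before
    for k, lid in enumerate(mus_ids):
        s_atom = npm.ligands[lid].endgroup_atoms[0]
        s_xyz = np_pos[s_atom]
        # Count from the placement target, not the jittered position, so a
        # trajectory at fixed distribution has a constant atom count.
        n_w = _shell_count(params, float(dz_mag[k]))
        shell = _shell_waters(rng_static, s_xyz, params.shell_radius, n_w)
        water_blocks.append(shell + _jitter(rng, params.noise_sigma,
                                            shell.shape))
        shells.append((lid, cursor, n_w))
        cursor += n_w
    if water_blocks:
        positions.append(np.concatenate(water_blocks, axis=0))
        roles.append(np.full(cursor - n_before, int(Role.WATER_O), int))

    frame = Frame(
        np.concatenate(positions, axis=0),
        np.concatenate(roles),
        bilayer.box,
        time=frame_index * params.frame_spacing_ns,
        np_model=NPModel(center + [0.0, 0.0, core_h], npm.core_radius,
                         npm.ligands, np_pos, npm.roles),
        metadata={
            "params": params,
            "frame_index": frame_index,
            "signs": signs,
            "dz_targets": {lid: float(dz_mag[k])
                           for k, lid in enumerate(mus_ids)},
            "slots": {lid: (float(slots[k, 0]), float(slots[k, 1]))
                      for k, lid in enumerate(mus_ids)},
            "shells": shells,
            "n_nonwater": n_before,
        },
    )
    return frame.wrapped_xy()


def gen_trajectory(params: GeneratorParams) -> list[Frame]:
    """``params.n_frames`` frames at a fixed distribution, independent jitter."""
    return [gen_frame(params, i) for i in range(params.n_frames)]


def _require_synthetic(frame: Frame) -> GeneratorParams:
    md = frame.metadata
    if frame.np_model is None or "shells" not in md or "params" not in md:
        raise FlipError("frame lacks synthetic-generator provenance")
    return md["params"]


def flip_ligand_synthetic(frame: Frame, ligand_id: int, seed: int) -> Frame:
    """Reflect one charged end group across the midplane and rebuild its shell.

    The ligand must currently sit above the midplane (d_z > 0); flipping an
    already-negative ligand is rejected.  All atoms other than the flipped
    end group and its hydration waters are untouched; water indices after
    the rebuilt shell shift if the shell size changes.
    """
    from .flipping import compute_dz  # local import to avoid a cycle

    params = _require_synthetic(frame)
    npm = frame.np_model
    lig = npm.ligands[ligand_id]
    if lig.kind is not LigandKind.MUS:
        raise FlipError(f"ligand {ligand_id} has no charged end group")
    dz = compute_dz(frame, ligand_id)
    if dz <= 0:
        raise FlipError(
            f"ligand {ligand_id} has d_z = {dz:.3f} <= 0; only ligands above "
            "the midplane can be flipped"
        )
    mid = midplane_z(frame)
    rng = np.random.default_rng([seed, 777, ligand_id])

    new_pos = frame.positions.copy()
    s_atom = lig.endgroup_atoms[0]
    old_s = frame.positions[s_atom]
    new_s = np.array([old_s[0], old_s[1], 2.0 * mid - old_s[2]])
    group = sulfonate_atoms(new_s, np.array([0.0, 0.0, -1.0]))
    group += _jitter(rng, params.noise_sigma, group.shape)
    new_pos[lig.endgroup_atoms] = group

    # Rebuild the water block: every shell kept verbatim except this ligand's.
    n_nonwater = frame.metadata["n_nonwater"]
    shells: list[tuple[int, int, int]] = frame.metadata["shells"]
    new_shells = []
    blocks = []
    cursor = n_nonwater
    for lid, start, count in shells:
        if lid == ligand_id:
            s_xyz = new_pos[s_atom]
            n_w = _shell_count(params, frame.metadata["dz_targets"][ligand_id])
            blocks.append(_shell_waters(rng, s_xyz, params.shell_radius, n_w))
        else:
            n_w = count
            blocks.append(frame.positions[start:start + count])
        new_shells.append((lid, cursor, n_w))
        cursor += n_w
    water = (np.concatenate(blocks, axis=0) if blocks
             else np.zeros((0, 3)))

    positions = np.concatenate([new_pos[:n_nonwater], water], axis=0)
    roles = np.concatenate([frame.roles[:n_nonwater],
                            np.full(len(water), int(Role.WATER_O), int)])
    signs = dict(frame.metadata["signs"])
    signs[ligand_id] = -1.0
    new_npm = NPModel(npm.core_center.copy(), npm.core_radius, npm.ligands,
                      npm.positions.copy(), npm.roles.copy())
    new_npm.positions[lig.endgroup_atoms] = group
    metadata = dict(frame.metadata)
    metadata.update(signs=signs, shells=new_shells)
    return Frame(positions, roles, frame.box.copy(), time=frame.time,
                 np_model=new_npm, metadata=metadata)


def resample_frames(frame: Frame, n_frames: int, seed: int) -> list[Frame]:
    """Equilibrium-like re-jitters of a frame (end groups and shell waters).

    Stands in for the post-flip sampling window: every copy jitters the
    charged end groups and their hydration waters about the frame's current
    positions, leaving the rest of the system fixed, so per-ligand mean
    d_z over the copies estimates the frame's d_z.
    """
    params = _require_synthetic(frame)
    npm = frame.np_model
    moving = np.zeros(frame.n_atoms, dtype=bool)
    for lig in npm.ligands:
        moving[lig.endgroup_atoms] = True
    moving[frame.metadata["n_nonwater"]:] = True

    out = []
    for i in range(n_frames):
        rng = np.random.default_rng([seed, 555, i])
        pos = frame.positions.copy()
        pos[moving] += _jitter(rng, params.noise_sigma,
                               (int(moving.sum()), 3))
        out.append(replace(frame, positions=pos, radii=frame.radii.copy(),
                           time=frame.time + i * params.frame_spacing_ns,
                           metadata=dict(frame.metadata)))
    return out
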