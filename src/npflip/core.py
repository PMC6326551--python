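"""Core geometry: atom roles, frames, and builders for the NP and bilayer.

The package models a monolayer-protected gold nanoparticle (NP) — a 2 nm
core grafted with a 1:1 mixture of MUS (11-mercaptoundecanesulfonate, an
11-carbon backbone ending in an anionic sulfonate) and OT (octanethiol,
8 carbons, purely hydrophobic) — interacting with a phosphatidylcholine
bilayer.  Geometry is deliberately coarse: every analysis in this package
consumes positions, roles and van der Waals radii only, so lipids are
reduced to head beads (choline N, phosphate P) plus tail beads, and ligand
backbones to extended chains.  Units are nm throughout; energies are
kcal/mol unless a field says otherwise.

Coordinate conventions: the bilayer normal is z, the "upper" leaflet is at
positive z (the side holding all 29 charged end groups in the initial
29+/0- state), and boxes are orthorhombic with periodicity in x and y.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import (
    CompositionError,
    UndefinedMidplaneError,
    UnsupportedCaseError,
)

__all__ = [
    "Role",
    "LigandKind",
    "Leaflet",
    "AtomRecord",
    "Frame",
    "Ligand",
    "NPModel",
    "BilayerModel",
    "DEFAULT_VDW_RADII",
    "ENDGROUP_MASSES",
    "SOLVENT_ROLES",
    "fibonacci_sphere",
    "build_np",
    "build_bilayer",
    "midplane_z",
    "assign_leaflets",
    "ion_counts",
]


class Role(enum.IntEnum):
    """Chemical role of an atom; the closed vocabulary of every analysis."""

    GOLD = 0
    THIOL_S = 1
    LIGAND_C_MUS = 2
    LIGAND_C_OT = 3
    SULFONATE_S = 4
    SULFONATE_O = 5
    CHOLINE_N = 6
    PHOSPHATE_P = 7
    LIPID_TAIL = 8
    WATER_O = 9
    ION_NA = 10
    ION_CL = 11


class LigandKind(str, enum.Enum):
    MUS = "MUS"
    OT = "OT"


class Leaflet(str, enum.Enum):
    UPPER = "UPPER"
    LOWER = "LOWER"


#: Default van der Waals radii (nm) by role.  A single documented set,
#: overridable wherever a radii table is accepted; ionic radii are included
#: so that every role has a positive radius even though ions never act as
#: SASA occluders by default.
DEFAULT_VDW_RADII: dict[Role, float] = {
    Role.GOLD: 0.166,
    Role.THIOL_S: 0.180,
    Role.LIGAND_C_MUS: 0.170,
    Role.LIGAND_C_OT: 0.170,
    Role.SULFONATE_S: 0.180,
    Role.SULFONATE_O: 0.152,
    Role.CHOLINE_N: 0.155,
    Role.PHOSPHATE_P: 0.180,
    Role.LIPID_TAIL: 0.170,
    Role.WATER_O: 0.152,
    Role.ION_NA: 0.227,
    Role.ION_CL: 0.181,
}

#: Atomic masses (u) used for the sulfonate end-group center of mass.
ENDGROUP_MASSES: dict[Role, float] = {
    Role.SULFONATE_S: 32.06,
    Role.SULFONATE_O: 15.999,
}

#: Roles treated as solvent: they define the probe, never occlude SASA.
SOLVENT_ROLES: frozenset[Role] = frozenset(
    {Role.WATER_O, Role.ION_NA, Role.ION_CL}
)

# Extended-chain C-C spacing (nm) and terminal S-O bond length (nm).
BACKBONE_SPACING = 0.127
SO_BOND = 0.149

# MUS/OT backbone lengths in carbons.
MUS_BACKBONE = 11
OT_BACKBONE = 8


@dataclass(frozen=True)
class AtomRecord:
    """Single-atom view: index into a frame, role, position (nm), radius (nm)."""

    index: int
    role: Role
    position: np.ndarray
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"atom {self.index}: radius must be > 0")
        Role(self.role)


def _radii_for(roles: np.ndarray, table: Mapping[Role, float]) -> np.ndarray:
    lut = np.empty(len(Role), dtype=float)
    lut.fill(np.nan)
    for role, r in table.items():
        lut[int(role)] = r
    out = lut[roles]
    if np.isnan(out).any():
        missing = sorted({Role(r).name for r in np.unique(roles[np.isnan(out)])})
        raise ValueError(f"no van der Waals radius for roles: {missing}")
    return out


@dataclass
class Frame:
    """One configuration: positions (N,3) nm, per-atom roles, orthorhombic box.

    ``np_model`` (when present) carries the NP topology whose ligand atom
    indices refer to this frame's numbering; ``metadata`` is free-form
    provenance (generator parameters, hydration-shell bookkeeping, time
    windows) that analyses may consult but never require.
    """

    positions: np.ndarray
    roles: np.ndarray
    box: np.ndarray
    time: float = 0.0
    radii: np.ndarray | None = None
    np_model: "NPModel | None" = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.roles = np.asarray(self.roles, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.roles.shape != (self.positions.shape[0],):
            raise ValueError("roles must have shape (N,)")
        if self.box.shape != (3,) or not (self.box > 0).all():
            raise ValueError("box must be 3 positive edge lengths (nm)")
        if self.roles.size and (
            self.roles.min() < 0 or self.roles.max() >= len(Role)
        ):
            raise ValueError("roles contain values outside the closed vocabulary")
        if self.radii is None:
            self.radii = _radii_for(self.roles, DEFAULT_VDW_RADII)
        else:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != self.roles.shape:
                raise ValueError("radii must align with roles")
            if self.radii.size and self.radii.min() <= 0:
                raise ValueError("all radii must be > 0")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def mask(self, *roles: Role) -> np.ndarray:
        """Boolean mask selecting atoms with any of the given roles."""
        return np.isin(self.roles, [int(r) for r in roles])

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(i, Role(self.roles[i]), self.positions[i].copy(),
                          float(self.radii[i]))

    def iter_atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield self.atom(i)

    def wrapped_xy(self) -> "Frame":
        """Copy with x, y wrapped into [0, box); z left untouched."""
        pos = self.positions.copy()
        pos[:, :2] = np.mod(pos[:, :2], self.box[:2])
        return replace(self, positions=pos, radii=self.radii.copy())

    def translated(self, shift) -> "Frame":
        shift = np.asarray(shift, dtype=float)
        npm = self.np_model.translated(shift) if self.np_model else None
        return replace(self, positions=self.positions + shift,
                       radii=self.radii.copy(), np_model=npm)


@dataclass
class Ligand:
    """One grafted ligand: kind, graft direction, and frame atom indices."""

    kind: LigandKind
    graft_direction: np.ndarray
    backbone_atoms: list[int]
    endgroup_atoms: list[int]
    anchor_atom: int

    def __post_init__(self):
        self.graft_direction = np.asarray(self.graft_direction, dtype=float)
        if abs(np.linalg.norm(self.graft_direction) - 1.0) > 1e-9:
            raise ValueError("graft_direction must be a unit vector")
        if self.kind is LigandKind.MUS:
            if len(self.backbone_atoms) != MUS_BACKBONE or not self.endgroup_atoms:
                raise ValueError("MUS needs 11 backbone carbons and an end group")
        else:
            if len(self.backbone_atoms) != OT_BACKBONE or self.endgroup_atoms:
                raise ValueError("OT needs 8 backbone carbons and no end group")

    def shifted(self, offset: int) -> "Ligand":
        return Ligand(self.kind, self.graft_direction.copy(),
                      [a + offset for a in self.backbone_atoms],
                      [a + offset for a in self.endgroup_atoms],
                      self.anchor_atom + offset)


@dataclass
class NPModel:
    """NP core plus grafted monolayer, with its own atom table.

    Ligand atom indices refer to ``positions``/``roles``; when the NP is
    embedded at the head of a larger frame the same indices remain valid.
    """

    core_center: np.ndarray
    core_radius: float
    ligands: list[Ligand]
    positions: np.ndarray
    roles: np.ndarray

    def __post_init__(self):
        self.core_center = np.asarray(self.core_center, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.roles = np.asarray(self.roles, dtype=np.int64)

    @property
    def n_mus(self) -> int:
        return sum(1 for l in self.ligands if l.kind is LigandKind.MUS)

    @property
    def net_charge(self) -> int:
        """Elementary charges: one anionic sulfonate per MUS ligand."""
        return -self.n_mus

    @property
    def grafting_density(self) -> float:
        """Ligands per nm^2 of core surface."""
        return len(self.ligands) / (4.0 * math.pi * self.core_radius**2)

    def mus_ligand_ids(self) -> list[int]:
        return [i for i, l in enumerate(self.ligands)
                if l.kind is LigandKind.MUS]

    def translated(self, shift) -> "NPModel":
        shift = np.asarray(shift, dtype=float)
        return NPModel(self.core_center + shift, self.core_radius,
                       list(self.ligands), self.positions + shift,
                       self.roles.copy())

    def to_frame(self, box=(12.0, 12.0, 12.0)) -> Frame:
        """The bare NP as a standalone frame (its own atom numbering)."""
        return Frame(self.positions.copy(), self.roles.copy(),
                     np.asarray(box, float), np_model=self)


@dataclass
class BilayerModel:
    """Leaflet assignment summary: one label per lipid (phosphate proxy)."""

    leaflet_of_lipid: list[Leaflet]
    midplane_z: float
    n_lipids: int

    def __post_init__(self):
        if self.n_lipids != len(self.leaflet_of_lipid):
            raise ValueError("n_lipids must equal the number of assignments")

    def leaflet_counts(self) -> tuple[int, int]:
        up = sum(1 for l in self.leaflet_of_lipid if l is Leaflet.UPPER)
        return up, self.n_lipids - up


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors from the golden-angle (Fibonacci) lattice.

    Deterministic; nearest-neighbor spacing varies by well under 30% across
    points, which is all the grafting and quadrature code needs.
    """
    if n <= 0:
        return np.zeros((0, 3))
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _orthonormal_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``direction`` to a right-handed frame."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(direction @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def sulfonate_atoms(s_position: np.ndarray, direction: np.ndarray):
    """Positions of S plus a tripod of three O, pointing along ``direction``."""
    e1, e2 = _orthonormal_basis(direction)
    # O tripod at ~70 deg off the outward axis, tetrahedral-ish.
    alpha = math.radians(70.0)
    pts = [s_position]
    for k in range(3):
        ang = 2.0 * math.pi * k / 3.0
        off = (math.sin(alpha) * (math.cos(ang) * e1 + math.sin(ang) * e2)
               + math.cos(alpha) * direction)
        pts.append(s_position + SO_BOND * off)
    return np.array(pts)


def build_np(core_diameter: float, n_ligands: int, mus_fraction: float,
             seed: int, *, n_core_beads: int = 92) -> NPModel:
    """Build the monolayer-protected NP.

    Graft points are a deterministic Fibonacci lattice on the core sphere;
    MUS/OT identities are assigned by a seeded shuffle.  Backbone carbons
    are placed collinearly along the graft direction at 0.127 nm spacing
    (an extended-chain stand-in), MUS chains terminated by a sulfonate
    (S + 3 O).  The hollow gold core is represented by ``n_core_beads``
    surface beads.  58 ligands on a 2 nm core give the experimental
    grafting density of 4.62 ligands/nm^2.
    """
    if core_diameter <= 0:
        raise CompositionError("core_diameter must be > 0")
    if not 0.0 <= mus_fraction <= 1.0:
        raise CompositionError("mus_fraction must lie in [0, 1]")
    n_mus_f = n_ligands * mus_fraction
    n_mus = round(n_mus_f)
    if abs(n_mus_f - n_mus) > 1e-9:
        raise CompositionError(
            f"n_ligands * mus_fraction = {n_mus_f} is not an integer"
        )
    radius = core_diameter / 2.0

    kinds = [LigandKind.MUS] * n_mus + [LigandKind.OT] * (n_ligands - n_mus)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_ligands) if n_ligands else np.array([], int)
    kinds = [kinds[i] for i in order]

    positions: list[np.ndarray] = []
    roles: list[int] = []

    core = fibonacci_sphere(n_core_beads) * radius
    positions.extend(core)
    roles.extend([int(Role.GOLD)] * n_core_beads)

    ligands: list[Ligand] = []
    directions = fibonacci_sphere(n_ligands)
    for kind, direction in zip(kinds, directions):
        anchor = len(positions)
        positions.append(direction * radius)
        roles.append(int(Role.THIOL_S))
        n_back = MUS_BACKBONE if kind is LigandKind.MUS else OT_BACKBONE
        backbone = []
        for j in range(n_back):
            backbone.append(len(positions))
            positions.append(direction * (radius + (j + 1) * BACKBONE_SPACING))
            roles.append(int(Role.LIGAND_C_MUS if kind is LigandKind.MUS
                             else Role.LIGAND_C_OT))
        endgroup: list[int] = []
        if kind is LigandKind.MUS:
            s_pos = direction * (radius + (n_back + 1) * BACKBONE_SPACING)
            for p, role in zip(sulfonate_atoms(s_pos, direction),
                               [Role.SULFONATE_S] + [Role.SULFONATE_O] * 3):
                endgroup.append(len(positions))
                positions.append(p)
                roles.append(int(role))
        ligands.append(Ligand(kind, direction, backbone, endgroup, anchor))

    pos = (np.array(positions).reshape(-1, 3)
           if positions else np.zeros((0, 3)))
    return NPModel(np.zeros(3), radius, ligands, pos, np.array(roles, int))


#: Lipid bead z-offsets (nm) relative to the leaflet's phosphate plane,
#: positive pointing out of the bilayer.  Phosphate defines the plane;
#: choline sits outward, two tail beads point toward the midplane.
_LIPID_BEADS = (
    (Role.CHOLINE_N, 0.35),
    (Role.PHOSPHATE_P, 0.0),
    (Role.LIPID_TAIL, -0.80),
    (Role.LIPID_TAIL, -1.50),
)

#: Default phosphate-plane half-separation (nm); ~3.8 nm P-P thickness.
DEFAULT_HEAD_OFFSET = 1.9


def ligand_extent(np_model: NPModel) -> float:
    """Radial reach of the monolayer from the core center (nm)."""
    longest = max((len(l.backbone_atoms) for l in np_model.ligands), default=0)
    reach = np_model.core_radius + (longest + 1) * BACKBONE_SPACING
    if any(l.kind is LigandKind.MUS for l in np_model.ligands):
        reach += SO_BOND
    return reach


def build_bilayer(n_lipids: int, area_per_lipid: float,
                  gap_for_np: NPModel | None = None, *,
                  head_offset: float = DEFAULT_HEAD_OFFSET,
                  box_z: float | None = None,
                  exclusion_radius: float | None = None) -> Frame:
    """Simplified bead bilayer: two leaflets of (choline, phosphate, 2 tails).

    Lipids occupy a square lattice with the requested area per lipid,
    head planes at ±``head_offset`` about z = 0.  When an NP model is
    supplied, a cylindrical gap around its core axis is left empty in any
    leaflet whose head plane overlaps the NP volume, so leaflet counts may
    differ and the total can drop below ``n_lipids``.
    """
    if area_per_lipid <= 0:
        raise CompositionError("area_per_lipid must be > 0")
    if n_lipids < 0:
        raise CompositionError("n_lipids must be >= 0")
    if gap_for_np is None and n_lipids % 2:
        raise CompositionError("n_lipids must be even without an NP gap")

    per_leaflet = (n_lipids + 1) // 2 if gap_for_np is not None else n_lipids // 2
    excl_area = 0.0
    if gap_for_np is not None:
        if exclusion_radius is None:
            exclusion_radius = ligand_extent(gap_for_np) + 0.7
        excl_area = math.pi * exclusion_radius**2
    area = max(per_leaflet, 1) * area_per_lipid + excl_area
    edge = math.sqrt(area)
    spacing = math.sqrt(area_per_lipid)
    if box_z is None:
        box_z = 2.0 * (head_offset + 3.0)
    box = np.array([edge, edge, box_z])
    center = box / 2.0

    # Candidate lattice sites, centered, sorted by radius for a compact
    # fill; sites beyond the box fold back under the xy wrap, which only
    # matters when an NP gap inflates the occupied area.
    n_side = 2 * int(math.ceil(edge / spacing)) + 3
    ax = (np.arange(n_side) - (n_side - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(ax, ax)
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    # Chebyshev-ring ordering fills concentric squares, matching the box.
    order = np.lexsort((np.hypot(sites[:, 0], sites[:, 1]),
                        np.abs(sites).max(axis=1)))
    sites = sites[order]

    positions: list[np.ndarray] = []
    roles: list[int] = []
    for sign in (+1.0, -1.0):
        plane_z = sign * head_offset
        skip_gap = False
        if gap_for_np is not None:
            # NP coordinates are bilayer-relative: midplane z = 0, axis x = y = 0.
            dz_np = abs(plane_z - gap_for_np.core_center[2])
            skip_gap = dz_np < ligand_extent(gap_for_np) + 0.35
        placed = 0
        for sx, sy in sites:
            if placed >= per_leaflet:
                break
            if skip_gap and math.hypot(sx, sy) < exclusion_radius:
                continue
            for role, off in _LIPID_BEADS:
                positions.append(np.array([sx, sy, plane_z + sign * off]))
                roles.append(int(role))
            placed += 1

    pos = np.array(positions).reshape(-1, 3) + center
    frame = Frame(pos, np.array(roles, int), box)
    return frame.wrapped_xy()


def midplane_z(frame: Frame) -> float:
    """Bilayer midplane: midpoint of the mean phosphate z of each leaflet.

    Leaflets are split about the overall mean phosphate z; a frame whose
    phosphates all fall on one side has no midplane and raises.
    """
    pz = frame.positions[frame.mask(Role.PHOSPHATE_P), 2]
    if pz.size < 2:
        raise UndefinedMidplaneError("need phosphates in both leaflets")
    cut = pz.mean()
    upper, lower = pz[pz > cut], pz[pz < cut]
    if upper.size == 0 or lower.size == 0:
        raise UndefinedMidplaneError("all phosphates lie in one leaflet")
    return 0.5 * (upper.mean() + lower.mean())


def assign_leaflets(frame: Frame) -> BilayerModel:
    """Per-lipid leaflet labels, one lipid per phosphate bead."""
    mid = midplane_z(frame)
    pz = frame.positions[frame.mask(Role.PHOSPHATE_P), 2]
    labels = [Leaflet.UPPER if z > mid else Leaflet.LOWER for z in pz]
    return BilayerModel(labels, mid, len(labels))


#: Molarity of pure water (mol/L), for the mole-fraction salt formula.
WATER_MOLARITY = 55.5


def ion_counts(n_water: int, np_net_charge: int, target_conc: float,
               n_cl_override: int | None = None) -> tuple[int, int]:
    """Na+/Cl- counts giving the target salt concentration, electroneutral.

    Cl- from the mole-fraction formula round(conc * n_water / 55.5 M)
    unless overridden; Na+ = Cl- plus the counter-ions neutralizing the
    anionic NP.  The published system (21,418 waters, charge -29, 150 mM
    with 60 Cl-) yields 89 Na+ and 60 Cl-.
    """
    if n_water <= 0:
        raise CompositionError("n_water must be > 0")
    if np_net_charge > 0:
        raise UnsupportedCaseError(
            "cationic NPs are not supported by this anionic-ligand convention"
        )
    n_cl = (int(n_cl_override) if n_cl_override is not None
            else round(target_conc * n_water / WATER_MOLARITY))
    if n_cl < 0:
        raise CompositionError("Cl- count must be >= 0")
    n_na = n_cl + max(0, -np_net_charge)
    assert n_na - n_cl + np_net_charge == 0  # electroneutrality by construction
    return n_na, n_cl
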