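"""Pair-distance statistics, density maps, trend fits, and error estimation.

Conventions: pair distances use the minimum-image convention in all three
box dimensions (the raw separation of two atoms), while quantities tied to
the bilayer normal — d_z, the cylindrical density maps — treat z as
non-periodic, since the bilayer breaks the z symmetry.  Contact and
coordination cutoffs come from the first minimum of the relevant radial
distribution function; 0.7 nm is the default for every polar role and is
meant to be overridden per species from configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .core import Frame, LigandKind, Role, midplane_z
from .errors import ConfigurationError, NoMinimumError

__all__ = [
    "RDFProfile",
    "ContactSummary",
    "CoordinationRecord",
    "RadialDensityMap",
    "POLAR_ROLES",
    "DEFAULT_POLAR_THRESHOLDS",
    "rdf",
    "first_min",
    "count_contacts",
    "coordination",
    "endgroup_coordination_table",
    "density_map",
    "core_depth_trend",
    "block_error",
]

#: Polar roles whose central atoms count toward end-group coordination.
POLAR_ROLES: frozenset[Role] = frozenset({
    Role.WATER_O, Role.CHOLINE_N, Role.PHOSPHATE_P, Role.SULFONATE_S,
    Role.ION_NA,
})

#: Shell cutoffs (nm) per polar role.  The published analysis reads each
#: from the first minimum of the species' RDF around a sulfonate; absent
#: tabulated values, every role defaults to the sulfonate-choline 0.7 nm
#: and should be overridden from config when better values are available.
DEFAULT_POLAR_THRESHOLDS: dict[Role, float] = {r: 0.7 for r in POLAR_ROLES}


@dataclass(frozen=True)
class RDFProfile:
    """g(r) on uniform bins, with the raw pair counts kept for reuse."""

    bin_centers: np.ndarray
    g_values: np.ndarray
    counts: np.ndarray
    dr: float

    def __post_init__(self):
        if (np.asarray(self.g_values) < 0).any():
            raise ValueError("g(r) must be >= 0")


@dataclass(frozen=True)
class ContactSummary:
    n_contacts: float
    error: float
    threshold: float = 0.7

    def __post_init__(self):
        if self.n_contacts < 0 or self.threshold <= 0:
            raise ValueError("invalid contact summary")


@dataclass(frozen=True)
class CoordinationRecord:
    """Time-averaged coordination of one end group, paired with its d_z."""

    ligand_id: int
    coordination_mean: float
    coordination_error: float
    dz_mean: float
    dz_error: float

    def __post_init__(self):
        if self.coordination_mean < 0:
            raise ValueError("coordination must be >= 0")


@dataclass(frozen=True)
class RadialDensityMap:
    """Cylindrically averaged number density about the NP axis.

    ``density[i, j]`` is the mean atom count in the annular bin
    (radial_edges[i:i+2], z_edges[j:j+2]) divided by its volume
    2 pi r_mid dr dz — number per nm^3.
    """

    radial_edges: np.ndarray
    z_edges: np.ndarray
    density: np.ndarray

    def bin_volumes(self) -> np.ndarray:
        r = np.asarray(self.radial_edges)
        z = np.asarray(self.z_edges)
        r_mid = 0.5 * (r[1:] + r[:-1])
        return (2.0 * math.pi * r_mid * np.diff(r))[:, None] * np.diff(z)[None, :]


def _min_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    return disp - box * np.round(disp / box)


def _pair_distances(pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray,
                    exclude_same: np.ndarray | None = None) -> np.ndarray:
    """All minimum-image A-B distances, optionally masking identical atoms."""
    disp = pos_a[:, None, :] - pos_b[None, :, :]
    disp = _min_image(disp, box)
    d = np.sqrt((disp ** 2).sum(-1))
    if exclude_same is not None:
        d[exclude_same] = np.inf
    return d


def rdf(frames: Sequence[Frame], roles_a: Sequence[Role],
        roles_b: Sequence[Role], dr: float, r_max: float) -> RDFProfile:
    """Radial distribution of roles_b atoms about roles_a atoms.

    Minimum-image in x, y and z; normalized by the ideal-gas expectation at
    the frame's roles_b number density and averaged over frames.
    """
    if dr <= 0:
        raise ConfigurationError("dr must be > 0")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    if len(edges) < 2:
        raise ConfigurationError("r_max must exceed dr")
    counts = np.zeros(len(edges) - 1)
    norm = 0.0
    for frame in frames:
        box = frame.box
        if r_max > box.min() / 2 + 1e-9:
            raise ConfigurationError(
                "r_max exceeds half the smallest box edge")
        ia = np.flatnonzero(frame.mask(*roles_a))
        ib = np.flatnonzero(frame.mask(*roles_b))
        if ia.size == 0 or ib.size == 0:
            raise ConfigurationError("both role sets must be nonempty")
        same = (ia[:, None] == ib[None, :])
        d = _pair_distances(frame.positions[ia], frame.positions[ib], box,
                            exclude_same=same)
        counts += np.histogram(d[np.isfinite(d)], bins=edges)[0]
        rho_b = ib.size / box.prod()
        norm += ia.size * rho_b
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (norm * shell_vol)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(centers, g, counts, dr)


def first_min(profile: RDFProfile, smooth_window: int = 3) -> float:
    """Bin center of the first local minimum after the first maximum of g(r).

    A centered moving average (``smooth_window`` bins) is applied first;
    a window of 1 disables smoothing.  Monotone profiles have no minimum.
    """
    if smooth_window < 1:
        raise ConfigurationError("smooth_window must be >= 1")
    g = np.asarray(profile.g_values, dtype=float)
    if smooth_window > 1:
        g = uniform_filter1d(g, smooth_window, mode="nearest")
    # first strict local maximum
    imax = None
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1]:
            imax = i
            break
    if imax is None:
        raise NoMinimumError("profile has no interior maximum")
    for i in range(imax + 1, len(g) - 1):
        if g[i] < g[i - 1] and g[i] <= g[i + 1]:
            return float(profile.bin_centers[i])
    raise NoMinimumError("no local minimum follows the first maximum")


def _block_or_naive(series: np.ndarray) -> float:
    n = len(series)
    if n >= 4:
        return block_error(series)
    if n > 1:
        return float(series.std(ddof=1) / math.sqrt(n))
    return 0.0


def count_contacts(frames: Sequence[Frame],
                   threshold: float = 0.7) -> ContactSummary:
    """Mean number of sulfonate S - choline N pairs within the cutoff.

    A contact is an (S, N) pair whose minimum-image distance is below
    ``threshold`` (0.7 nm, the sulfonate-choline RDF first minimum).
    """
    per_frame = []
    for frame in frames:
        s = frame.positions[frame.mask(Role.SULFONATE_S)]
        n = frame.positions[frame.mask(Role.CHOLINE_N)]
        if s.size == 0 or n.size == 0:
            per_frame.append(0)
            continue
        d = _pair_distances(s, n, frame.box)
        per_frame.append(int((d < threshold).sum()))
    series = np.asarray(per_frame, dtype=float)
    return ContactSummary(float(series.mean()), _block_or_naive(series),
                          threshold)


def coordination(frames: Sequence[Frame], ligand_id: int,
                 thresholds: Mapping[Role, float] | None = None
                 ) -> CoordinationRecord:
    """Polar coordination number of one end group, averaged over frames.

    Counts, per frame, the polar central atoms (water O, choline N,
    phosphate P, other sulfonate S, Na+) within each role's cutoff of the
    ligand's sulfonate sulfur, excluding the ligand's own end-group atoms.
    Any polar role present in a frame must have a cutoff.
    """
    from .flipping import compute_dz

    thresholds = dict(thresholds if thresholds is not None
                      else DEFAULT_POLAR_THRESHOLDS)
    coord = []
    dz = []
    for frame in frames:
        lig = frame.np_model.ligands[ligand_id]
        if lig.kind is not LigandKind.MUS:
            raise ConfigurationError("coordination is defined for MUS ligands")
        s_idx = lig.endgroup_atoms[0]
        own = set(lig.endgroup_atoms)
        present = POLAR_ROLES & {Role(r) for r in np.unique(frame.roles)}
        missing = present - set(thresholds)
        if missing:
            raise ConfigurationError(
                f"no threshold for polar roles: {sorted(r.name for r in missing)}")
        total = 0
        center = frame.positions[s_idx]
        for role in present:
            idx = np.flatnonzero(frame.mask(role))
            idx = idx[[i not in own for i in idx]]
            if idx.size == 0:
                continue
            disp = _min_image(frame.positions[idx] - center, frame.box)
            d = np.sqrt((disp ** 2).sum(-1))
            total += int((d < thresholds[role]).sum())
        coord.append(total)
        dz.append(compute_dz(frame, ligand_id))
    coord = np.asarray(coord, dtype=float)
    dz = np.asarray(dz, dtype=float)
    return CoordinationRecord(ligand_id, float(coord.mean()),
                              _block_or_naive(coord), float(dz.mean()),
                              _block_or_naive(dz))


def density_map(frames: Sequence[Frame], roles: Sequence[Role],
                dr: float, dz: float, r_max: float | None = None,
                z_max: float | None = None) -> RadialDensityMap:
    """Cylindrical number-density map about the NP core axis.

    Radial distance is measured in the xy plane from the core center
    (minimum image); z is measured from the bilayer midplane, non-periodic.
    Densities are per nm^3: counts / (n_frames * 2 pi r dr dz).
    """
    if dr <= 0 or dz <= 0:
        raise ConfigurationError("bin widths must be > 0")
    if not frames:
        raise ConfigurationError("need at least one frame")
    box = frames[0].box
    if r_max is None:
        r_max = float(box[:2].min()) / 2.0
    if z_max is None:
        z_max = float(box[2]) / 2.0
    r_edges = np.arange(0.0, r_max + dr / 2, dr)
    z_edges = np.arange(-z_max, z_max + dz / 2, dz)
    hist = np.zeros((len(r_edges) - 1, len(z_edges) - 1))
    for frame in frames:
        if frame.np_model is not None:
            axis = frame.np_model.core_center[:2]
        else:
            gold = frame.positions[frame.mask(Role.GOLD)]
            if gold.size == 0:
                raise ConfigurationError(
                    "no NP core present to define the cylindrical axis")
            axis = gold[:, :2].mean(axis=0)
        mid = midplane_z(frame)
        idx = np.flatnonzero(frame.mask(*roles))
        dxy = _min_image(frame.positions[idx, :2] - axis, frame.box[:2])
        r = np.hypot(dxy[:, 0], dxy[:, 1])
        zrel = frame.positions[idx, 2] - mid
        hist += np.histogram2d(r, zrel, bins=(r_edges, z_edges))[0]
    out = RadialDensityMap(r_edges, z_edges, np.zeros_like(hist))
    vol = out.bin_volumes()
    return RadialDensityMap(r_edges, z_edges, hist / (len(frames) * vol))


def endgroup_coordination_table(frames: Sequence[Frame],
                                thresholds: Mapping[Role, float] | None = None
                                ) -> list[CoordinationRecord]:
    """Role-based coordination for every sulfonate end group in a trajectory.

    For frames read from coordinate files (no ligand topology attached),
    end groups are identified as each sulfonate S plus its three nearest
    sulfonate O in the first frame.  Records are keyed by the sulfur's
    atom index instead of a ligand id.
    """
    thresholds = dict(thresholds if thresholds is not None
                      else DEFAULT_POLAR_THRESHOLDS)
    first = frames[0]
    s_idx = np.flatnonzero(first.mask(Role.SULFONATE_S))
    o_idx = np.flatnonzero(first.mask(Role.SULFONATE_O))
    groups = {}
    for s in s_idx:
        if o_idx.size:
            d = np.linalg.norm(first.positions[o_idx] - first.positions[s],
                               axis=1)
            own_o = o_idx[np.argsort(d)[:3]]
        else:
            own_o = np.array([], dtype=int)
        groups[int(s)] = set(own_o.tolist()) | {int(s)}

    records = []
    for s, own in groups.items():
        coord, dzs = [], []
        for frame in frames:
            mid = midplane_z(frame)
            present = POLAR_ROLES & {Role(r) for r in np.unique(frame.roles)}
            missing = present - set(thresholds)
            if missing:
                raise ConfigurationError(
                    "no threshold for polar roles: "
                    f"{sorted(r.name for r in missing)}")
            center = frame.positions[s]
            total = 0
            for role in present:
                idx = np.flatnonzero(frame.mask(role))
                idx = idx[[i not in own for i in idx]]
                if idx.size == 0:
                    continue
                disp = _min_image(frame.positions[idx] - center, frame.box)
                total += int((np.sqrt((disp ** 2).sum(-1))
                              < thresholds[role]).sum())
            coord.append(total)
            dzs.append(float(frame.positions[s, 2] - mid))
        coord = np.asarray(coord, dtype=float)
        dzs = np.asarray(dzs, dtype=float)
        records.append(CoordinationRecord(s, float(coord.mean()),
                                          _block_or_naive(coord),
                                          float(dzs.mean()),
                                          _block_or_naive(dzs)))
    return records


def core_depth_trend(per_distribution_depths: Sequence[tuple[float, float]]
                     ) -> tuple[float, float, np.ndarray]:
    """OLS fit of NP-core height above the midplane vs flips performed.

    Returns (slope, intercept, residuals).  The published trend is
    approximately linear: the core descends toward the midplane as
    charged ligands flip.
    """
    pts = np.asarray(per_distribution_depths, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ConfigurationError("need at least two (n_flipped, z) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ConfigurationError("need at least two distinct x values")
    fit = linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    return float(fit.slope), float(fit.intercept), residuals


def block_error(series: Sequence[float], plateau_rtol: float = 0.05) -> float:
    """Standard error of the mean of a (possibly correlated) series.

    Flyvbjerg-Petersen blocking: successive pairwise averaging, taking the
    first level where the estimate changes by less than ``plateau_rtol``
    over two successive levels.  Without a plateau the largest estimate is
    returned (a conservative bound for strongly correlated data).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ConfigurationError("blocking needs at least 4 samples")
    estimates = []
    while x.size >= 2:
        estimates.append(float(x.std(ddof=1) / math.sqrt(x.size)))
        if x.size < 4:
            break
        m = x.size // 2
        x = 0.5 * (x[: 2 * m : 2] + x[1 : 2 * m : 2])
    for k in range(len(estimates) - 2):
        e0, e1, e2 = estimates[k], estimates[k + 1], estimates[k + 2]
        scale = max(abs(e0), 1e-300)
        if (abs(e1 - e0) / scale < plateau_rtol
                and abs(e2 - e1) / max(abs(e1), 1e-300) < plateau_rtol):
            return e1
    return max(estimates)
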