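"""Iterative charged-ligand flipping: d_z, classification, selection, schedules.

The workflow mirrors how the insertion pathway is sampled: measure each
charged end group's signed height above the bilayer midplane (d_z), label
the configuration "n+/m-" by the sign of the per-ligand mean, pick the
ligand with the *smallest positive* mean d_z (closest to the flipping
transition state), emit a harmonic-bias pull schedule for it, flip it, and
repeat.  Fourteen flips take 29+/0- to the membrane-spanning 15+/14-.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ENDGROUP_MASSES, Frame, LigandKind, Role, midplane_z
from .errors import (
    AmbiguousClassificationError,
    ConfigurationError,
    FlipError,
    NoEndGroupError,
    TerminalStateError,
)

__all__ = [
    "DzRecord",
    "LigandDistribution",
    "BiasSchedule",
    "FlipStep",
    "compute_dz",
    "dz_records",
    "classify",
    "select_next",
    "make_bias_schedule",
    "write_schedule",
    "read_schedule",
    "run_flip_sequence",
]

KJ_PER_KCAL = 4.184


@dataclass(frozen=True)
class DzRecord:
    """Per-ligand mean d_z (nm) with a block-averaging error estimate."""

    ligand_id: int
    dz_mean: float
    dz_error: float
    n_frames: int

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.dz_error < 0:
            raise ValueError("dz_error must be >= 0")


@dataclass(frozen=True)
class LigandDistribution:
    """Counts of charged end groups above (+) and below (-) the midplane."""

    n_plus: int
    n_minus: int

    @property
    def label(self) -> str:
        return f"{self.n_plus}+/{self.n_minus}-"

    def mirrored(self) -> "LigandDistribution":
        return LigandDistribution(self.n_minus, self.n_plus)


@dataclass(frozen=True)
class BiasSchedule:
    """Harmonic pull prescription for one flip, engine-agnostic.

    The spring constant is stored in kJ/mol/nm^2 as conventionally printed
    for MD pull codes; ``spring_constant_kcal`` converts on output.
    Durations are ns.
    """

    ligand_id: int
    target_dz: float
    spring_constant: float = 3000.0
    pull_duration: float = 1.5
    equilibration: float = 20.0

    def __post_init__(self):
        if self.spring_constant <= 0:
            raise ConfigurationError("spring_constant must be > 0")
        if self.pull_duration <= 0:
            raise ConfigurationError("pull_duration must be > 0")
        if self.equilibration < 0:
            raise ConfigurationError("equilibration must be >= 0")

    @property
    def spring_constant_kcal(self) -> float:
        return self.spring_constant / KJ_PER_KCAL


@dataclass(frozen=True)
class FlipStep:
    """One entry of the flip sequence: state after the flip plus provenance."""

    distribution: LigandDistribution
    frame: Frame
    schedule: BiasSchedule
    ligand_id: int
    dz_before: float


def _mus_ligand(frame: Frame, ligand_id: int):
    if frame.np_model is None:
        raise ConfigurationError("frame carries no NP topology")
    lig = frame.np_model.ligands[ligand_id]
    if lig.kind is not LigandKind.MUS:
        raise NoEndGroupError(
            f"ligand {ligand_id} is {lig.kind.value}: no sulfonate end group"
        )
    return lig


def compute_dz(frame: Frame, ligand_id: int) -> float:
    """Signed height of a sulfonate end group's center of mass above the midplane.

    The center of mass is over the S + 3 O sulfonate atoms, mass-weighted;
    positive means the end group sits on the upper-leaflet side.
    """
    lig = _mus_ligand(frame, ligand_id)
    idx = np.asarray(lig.endgroup_atoms)
    masses = np.array([ENDGROUP_MASSES[Role(r)] for r in frame.roles[idx]])
    com_z = float(np.average(frame.positions[idx, 2], weights=masses))
    return com_z - midplane_z(frame)


def dz_records(frames: Sequence[Frame]) -> list[DzRecord]:
    """Mean d_z per charged ligand over frames, with block-averaged errors.

    For fewer than 4 frames (too short for the blocking transform) the
    naive standard error of the mean is reported instead.
    """
    from .analysis import block_error

    if not frames:
        raise ConfigurationError("need at least one frame")
    mus_ids = frames[0].np_model.mus_ligand_ids()
    records = []
    for lid in mus_ids:
        series = np.array([compute_dz(f, lid) for f in frames])
        n = len(series)
        if n >= 4:
            err = block_error(series)
        elif n > 1:
            err = float(series.std(ddof=1) / np.sqrt(n))
        else:
            err = 0.0
        records.append(DzRecord(lid, float(series.mean()), err, n))
    return records


def classify(frames: Frame | Sequence[Frame]) -> LigandDistribution:
    """Label a configuration "n+/m-" from per-ligand mean d_z signs.

    A ligand whose mean d_z is exactly zero cannot be assigned a side and
    raises; the caller must resolve the tie (e.g. by adding frames).
    """
    if isinstance(frames, Frame):
        frames = [frames]
    records = dz_records(frames)
    n_plus = n_minus = 0
    for rec in records:
        if rec.dz_mean > 0:
            n_plus += 1
        elif rec.dz_mean < 0:
            n_minus += 1
        else:
            raise AmbiguousClassificationError(
                f"ligand {rec.ligand_id} has mean d_z exactly 0"
            )
    return LigandDistribution(n_plus, n_minus)


def select_next(records: Sequence[DzRecord]) -> int:
    """The ligand with the smallest positive mean d_z (closest to flipping).

    Ties are broken by the smallest ligand id.  When no ligand has positive
    mean d_z the sequence has reached its terminal state.
    """
    positives = [r for r in records if r.dz_mean > 0]
    if not positives:
        raise TerminalStateError("no ligand with positive mean d_z remains")
    best = min(positives, key=lambda r: (r.dz_mean, r.ligand_id))
    return best.ligand_id


def make_bias_schedule(ligand_id: int, current_dz: float,
                       overrides: dict | None = None) -> BiasSchedule:
    """Pull schedule flipping a ligand to the mirror-image d_z."""
    if current_dz <= 0:
        raise FlipError("schedules are only defined for ligands with d_z > 0")
    kwargs = dict(ligand_id=ligand_id, target_dz=-current_dz)
    if overrides:
        allowed = {"spring_constant", "pull_duration", "equilibration",
                   "target_dz"}
        bad = set(overrides) - allowed
        if bad:
            raise ConfigurationError(f"unknown schedule overrides: {sorted(bad)}")
        kwargs.update(overrides)
    return BiasSchedule(**kwargs)


_SCHEDULE_KEYS = ("ligand_id", "group", "axis", "k_kj_mol_nm2",
                  "duration_ns", "equilibration_ns", "target_dz_nm")


def write_schedule(schedule: BiasSchedule, path) -> None:
    """Plain-text key=value restraint descriptor, one schedule per file."""
    lines = [
        f"ligand_id={schedule.ligand_id}",
        "group=sulfonate",
        "axis=z",
        f"k_kj_mol_nm2={schedule.spring_constant:.6g}",
        f"duration_ns={schedule.pull_duration:.6g}",
        f"equilibration_ns={schedule.equilibration:.6g}",
        f"target_dz_nm={schedule.target_dz:.6g}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_schedule(path) -> BiasSchedule:
    kv = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}: malformed line {i}: {line!r}")
        key, val = line.split("=", 1)
        kv[key.strip()] = val.strip()
    missing = set(_SCHEDULE_KEYS) - set(kv)
    if missing:
        raise ConfigurationError(f"{path}: missing keys {sorted(missing)}")
    return BiasSchedule(
        ligand_id=int(kv["ligand_id"]),
        target_dz=float(kv["target_dz_nm"]),
        spring_constant=float(kv["k_kj_mol_nm2"]),
        pull_duration=float(kv["duration_ns"]),
        equilibration=float(kv["equilibration_ns"]),
    )


def run_flip_sequence(initial: Frame, n_flips: int, seed: int, *,
                      n_eq_frames: int = 8,
                      schedule_overrides: dict | None = None) -> list[FlipStep]:
    """The 14-step workflow: classify, select, emit schedule, flip, repeat.

    ``initial`` must classify with every charged ligand above the midplane
    (the 29+/0- starting state).  Each iteration resamples an equilibrium
    window of ``n_eq_frames`` jittered frames to estimate per-ligand mean
    d_z, then flips the selected ligand.  Returns one entry per flip; a
    terminal-state signal propagates if positives run out early.
    """
    from .synthetic import flip_ligand_synthetic, resample_frames

    start = classify(initial)
    if start.n_minus != 0:
        raise FlipError(
            f"flip sequences start from an all-up state, got {start.label}"
        )
    steps: list[FlipStep] = []
    current = initial
    for step in range(n_flips):
        frames = resample_frames(current, n_eq_frames, seed + 104729 * step)
        records = dz_records(frames)
        selected = select_next(records)
        rec = next(r for r in records if r.ligand_id == selected)
        schedule = make_bias_schedule(selected, rec.dz_mean,
                                      schedule_overrides)
        current = flip_ligand_synthetic(current, selected, seed + step)
        steps.append(FlipStep(classify(current), current, schedule,
                              selected, rec.dz_mean))
    return steps
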