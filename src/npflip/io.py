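"""File formats: GRO/PDB coordinates (via mdtraj) and the role sidecar TSV.

GRO is the native format (fixed-column, nm — matching the package's
internal units); PDB is supported for interoperability, with the Angstrom
conversion handled at the boundary.  Atom roles are not expressible in
either format, so they travel in a TSV sidecar (``atom_index<TAB>role``)
or, for files this package wrote itself, in a bijective atom-naming
scheme that lets roles round-trip without the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import Frame, Role
from .errors import ConfigurationError, GroParseError

__all__ = [
    "ROLE_TO_ATOM_NAME",
    "read_gro",
    "write_gro",
    "read_pdb",
    "write_pdb",
    "read_labels",
    "write_labels",
    "apply_labels",
    "labels_from_frame",
    "write_provenance",
]

#: Bijective role <-> atom-name scheme used in files this package writes.
ROLE_TO_ATOM_NAME: dict[Role, str] = {
    Role.GOLD: "AU",
    Role.THIOL_S: "ST",
    Role.LIGAND_C_MUS: "CM",
    Role.LIGAND_C_OT: "CO",
    Role.SULFONATE_S: "S",
    Role.SULFONATE_O: "OS",
    Role.CHOLINE_N: "N",
    Role.PHOSPHATE_P: "P",
    Role.LIPID_TAIL: "CT",
    Role.WATER_O: "OW",
    Role.ION_NA: "NA",
    Role.ION_CL: "CL",
}
ATOM_NAME_TO_ROLE = {v: k for k, v in ROLE_TO_ATOM_NAME.items()}

_ROLE_ELEMENT = {
    Role.GOLD: "Au", Role.THIOL_S: "S", Role.LIGAND_C_MUS: "C",
    Role.LIGAND_C_OT: "C", Role.SULFONATE_S: "S", Role.SULFONATE_O: "O",
    Role.CHOLINE_N: "N", Role.PHOSPHATE_P: "P", Role.LIPID_TAIL: "C",
    Role.WATER_O: "O", Role.ION_NA: "Na", Role.ION_CL: "Cl",
}


def _validate_gro_text(path: Path) -> None:
    """Cheap structural scan so parse errors carry a line number."""
    lines = path.read_text().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip() and i == n_lines - 1:
            break
        if i + 1 >= n_lines:
            raise GroParseError("truncated frame: missing atom count", i + 2)
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise GroParseError(
                f"malformed atom count line: {lines[i + 1]!r}", i + 2)
        end = i + 2 + n_atoms
        if end >= n_lines:
            raise GroParseError(
                f"declared {n_atoms} atoms but file ends early", n_lines)
        i = end + 1  # past the box line


def _topology_for(roles: np.ndarray):
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    for i, code in enumerate(roles):
        role = Role(code)
        res = top.add_residue(_resname(role), chain)
        top.add_atom(ROLE_TO_ATOM_NAME[role],
                     md.element.get_by_symbol(_ROLE_ELEMENT[role]), res)
    return top


def _resname(role: Role) -> str:
    if role in (Role.GOLD, Role.THIOL_S, Role.LIGAND_C_MUS,
                Role.LIGAND_C_OT, Role.SULFONATE_S, Role.SULFONATE_O):
        return "NP"
    if role in (Role.CHOLINE_N, Role.PHOSPHATE_P, Role.LIPID_TAIL):
        return "LIP"
    if role is Role.WATER_O:
        return "SOL"
    return "ION"


def write_gro(frames: Frame | Sequence[Frame], path) -> None:
    """Write one or more frames as (multi-frame) GRO, 3-decimal nm."""
    import mdtraj as md

    if isinstance(frames, Frame):
        frames = [frames]
    if not frames:
        raise ConfigurationError("nothing to write")
    top = _topology_for(frames[0].roles)
    xyz = np.stack([f.positions for f in frames])
    lengths = np.stack([f.box for f in frames])
    angles = np.full((len(frames), 3), 90.0)
    traj = md.Trajectory(xyz, top, time=[f.time for f in frames],
                         unitcell_lengths=lengths, unitcell_angles=angles)
    traj.save_gro(str(path))


def read_gro(path, roles: Mapping[int, Role] | None = None) -> list[Frame]:
    """Read a (multi-frame) GRO file into Frames, in order.

    Roles come from the ``roles`` mapping (a labels sidecar) when given,
    else from the package's atom-naming scheme; unknown names without a
    sidecar are an error.
    """
    import mdtraj as md

    path = Path(path)
    _validate_gro_text(path)
    try:
        traj = md.load(str(path))
    except Exception as exc:  # mdtraj raises assorted types
        raise GroParseError(f"{path}: {exc}") from exc
    return _frames_from_traj(traj, roles, path)


_WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "SPC"}


def _frames_from_traj(traj, roles, path) -> list[Frame]:
    atoms = list(traj.topology.atoms)
    if roles is None:
        role_list = []
        for a in atoms:
            # readers may standardize water naming (SOL/OW -> HOH/O)
            if a.residue.name in _WATER_RESNAMES:
                role_list.append(int(Role.WATER_O))
            elif a.name in ATOM_NAME_TO_ROLE:
                role_list.append(int(ATOM_NAME_TO_ROLE[a.name]))
            else:
                raise ConfigurationError(
                    f"{path}: atom name {a.name!r} is not in the package "
                    "naming scheme; supply a labels sidecar")
        role_arr = np.array(role_list)
    else:
        missing = [i for i in range(traj.n_atoms) if i not in roles]
        if missing:
            raise ConfigurationError(
                f"{path}: labels missing for atom indices {missing[:5]}...")
        role_arr = np.array([int(roles[i]) for i in range(traj.n_atoms)])
    if traj.unitcell_lengths is None:
        raise GroParseError(f"{path}: no box information")
    return [Frame(traj.xyz[k].astype(float),
                  role_arr.copy(),
                  traj.unitcell_lengths[k].astype(float),
                  time=float(traj.time[k]) if traj.time is not None else 0.0)
            for k in range(traj.n_frames)]


def write_pdb(frames: Frame | Sequence[Frame], path) -> None:
    """PDB output; internal nm are converted to Angstrom by the writer."""
    import mdtraj as md

    if isinstance(frames, Frame):
        frames = [frames]
    top = _topology_for(frames[0].roles)
    xyz = np.stack([f.positions for f in frames])
    traj = md.Trajectory(
        xyz, top, time=[f.time for f in frames],
        unitcell_lengths=np.stack([f.box for f in frames]),
        unitcell_angles=np.full((len(frames), 3), 90.0))
    traj.save_pdb(str(path))


def read_pdb(path, roles: Mapping[int, Role] | None = None) -> list[Frame]:
    import mdtraj as md

    try:
        traj = md.load(str(path))
    except Exception as exc:
        raise GroParseError(f"{path}: {exc}") from exc
    return _frames_from_traj(traj, roles, path)


def write_labels(mapping: Mapping[int, Role], path) -> None:
    """Role sidecar: TSV with header ``atom_index<TAB>role``."""
    lines = ["atom_index\trole"]
    for idx in sorted(mapping):
        lines.append(f"{idx}\t{Role(mapping[idx]).name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path) -> dict[int, Role]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["atom_index", "role"]:
        raise ConfigurationError(f"{path}: missing 'atom_index\\trole' header")
    mapping: dict[int, Role] = {}
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(f"{path}: line {lineno}: expected 2 columns")
        try:
            idx = int(parts[0])
        except ValueError:
            raise ConfigurationError(
                f"{path}: line {lineno}: bad atom index {parts[0]!r}")
        if parts[1] not in Role.__members__:
            raise ConfigurationError(
                f"{path}: line {lineno}: unknown role {parts[1]!r}")
        if idx in mapping:
            raise ConfigurationError(
                f"{path}: line {lineno}: duplicate atom index {idx}")
        mapping[idx] = Role[parts[1]]
    return mapping


def apply_labels(frame: Frame, mapping: Mapping[int, Role]) -> Frame:
    """Frame with roles replaced from a sidecar; every atom must be covered."""
    missing = [i for i in range(frame.n_atoms) if i not in mapping]
    if missing:
        raise ConfigurationError(
            f"labels missing for {len(missing)} atoms (first: {missing[:5]})")
    roles = np.array([int(mapping[i]) for i in range(frame.n_atoms)])
    return Frame(frame.positions.copy(), roles, frame.box.copy(),
                 time=frame.time, metadata=dict(frame.metadata))


def labels_from_frame(frame: Frame) -> dict[int, Role]:
    return {i: Role(r) for i, r in enumerate(frame.roles)}


def write_provenance(path, **fields) -> None:
    """JSON sidecar echoing generator/analysis parameters for reproducibility."""
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if hasattr(obj, "__dataclass_fields__"):
            from dataclasses import asdict
            return asdict(obj)
        if isinstance(obj, Role):
            return obj.name
        return str(obj)

    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True,
                                     default=_default) + "\n")
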