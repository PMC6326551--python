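import math

import numpy as np
import pytest

import npflip as nf
from npflip.core import Frame, Ligand, LigandKind, NPModel, Role


@pytest.fixture(scope="session")
def np58():
    """The published NP: 2 nm core, 58 ligands, 1:1 MUS:OT."""
    return nf.build_np(2.0, 58, 0.5, seed=1)


@pytest.fixture(scope="session")
def params29():
    """Generator at the initial all-up distribution."""
    return nf.GeneratorParams(n_plus=29, n_minus=0, seed=1)


@pytest.fixture(scope="session")
def frame29(params29):
    return nf.gen_frame(params29, 0)


def toy_endgroup_frame(z_values, masses_equal=True, box=(10.0, 10.0, 10.0)):
    """Frame with one 'ligand' whose end group sits at given z values,
    plus a symmetric 4-phosphate bilayer so the midplane is z = 5."""
    mid = box[2] / 2.0
    pos = [[1.0, 1.0, mid + 1.9], [2.0, 1.0, mid + 1.9],
           [1.0, 1.0, mid - 1.9], [2.0, 1.0, mid - 1.9]]
    roles = [int(Role.PHOSPHATE_P)] * 4
    eg_idx = []
    for k, z in enumerate(z_values):
        eg_idx.append(len(pos))
        pos.append([5.0 + 0.01 * k, 5.0, mid + z])
        roles.append(int(Role.SULFONATE_S if masses_equal or k == 0
                         else Role.SULFONATE_O))
    # pad backbone with 11 carbons far away to satisfy the MUS invariant
    backbone = []
    for k in range(11):
        backbone.append(len(pos))
        pos.append([8.0, 8.0, 1.0 + 0.2 * k])
        roles.append(int(Role.LIGAND_C_MUS))
    lig = Ligand(LigandKind.MUS, np.array([0.0, 0.0, 1.0]),
                 backbone, eg_idx, anchor_atom=0)
    npm = NPModel(np.array([5.0, 5.0, mid]), 1.0, [lig],
                  np.array(pos), np.array(roles))
    return Frame(np.array(pos), np.array(roles), np.array(box),
                 np_model=npm), mid


def brute_force_sasa(frame, subset, params):
    """All-pairs Shrake-Rupley reference: no spatial index, no shortcuts."""
    from npflip.core import fibonacci_sphere

    table = params.radii_table
    r_exp = np.array([table[Role(r)] for r in frame.roles]) + params.probe_radius
    occ = ~np.isin(frame.roles, [int(r) for r in params.solvent_roles])
    pts = fibonacci_sphere(params.n_sphere_points)
    areas = []
    for i in subset:
        ri = r_exp[i]
        test = frame.positions[i] + ri * pts
        buried = np.zeros(len(test), dtype=bool)
        for j in np.flatnonzero(occ):
            if j == i:
                continue
            d2 = ((test - frame.positions[j]) ** 2).sum(axis=1)
            buried |= d2 < r_exp[j] ** 2
        areas.append((1.0 - buried.mean()) * 4 * math.pi * ri * ri)
    return np.array(areas)


def two_sphere_area(r1, r2, probe, d):
    """Closed-form accessible area of two overlapping probe-inflated spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * (R1 * R1 + R2 * R2)
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    a1 = 4 * math.pi * R1 * R1 - 2 * math.pi * R1 * max(h1, 0.0)
    a2 = 4 * math.pi * R2 * R2 - 2 * math.pi * R2 * max(h2, 0.0)
    return a1 + a2
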