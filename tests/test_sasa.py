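import math

import numpy as np
import pytest

import npflip as nf
from npflip.core import Frame, Role
from npflip.errors import ConfigurationError, TopologyMismatchError
from npflip.sasa import SasaParams, nonpolar_subset, shrake_rupley

from .conftest import brute_force_sasa, two_sphere_area

CARBON = {Role.LIGAND_C_MUS: 0.2}


def carbon_frame(positions, box=(20.0, 20.0, 20.0)):
    pos = np.atleast_2d(positions)
    return Frame(pos, np.full(len(pos), int(Role.LIGAND_C_MUS)), box)


class TestQuadrature:
    def test_isolated_sphere_closed_form(self):
        frame = carbon_frame([[10.0, 10.0, 10.0]])
        res = shrake_rupley(frame, [0], SasaParams(radii_table=CARBON))
        assert res.total_area == pytest.approx(4 * math.pi * 0.34 ** 2,
                                               rel=0.01)

    @pytest.mark.parametrize("d", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.67])
    def test_two_sphere_closed_form(self, d):
        frame = carbon_frame([[10, 10, 10], [10 + d, 10, 10]])
        res = shrake_rupley(frame, [0, 1], SasaParams(radii_table=CARBON))
        exact = two_sphere_area(0.2, 0.2, 0.14, d)
        assert res.total_area == pytest.approx(exact, rel=0.01)

    def test_unequal_radii_two_spheres(self):
        table = {Role.LIGAND_C_MUS: 0.2, Role.PHOSPHATE_P: 0.3}
        pos = np.array([[10, 10, 10], [10.35, 10, 10]])
        roles = np.array([int(Role.LIGAND_C_MUS), int(Role.PHOSPHATE_P)])
        frame = Frame(pos, roles, [20, 20, 20])
        res = shrake_rupley(frame, [0, 1], SasaParams(radii_table=table))
        assert res.total_area == pytest.approx(
            two_sphere_area(0.2, 0.3, 0.14, 0.35), rel=0.01)

    def test_quadrature_convergence_on_np(self, np58):
        frame = np58.to_frame()
        subset = nonpolar_subset(np58)
        a = shrake_rupley(frame, subset, SasaParams(n_sphere_points=960))
        b = shrake_rupley(frame, subset, SasaParams(n_sphere_points=3840))
        assert abs(a.total_area - b.total_area) / b.total_area < 0.005

    def test_rigid_motion_invariance(self, np58):
        from scipy.spatial.transform import Rotation

        frame = np58.to_frame()
        subset = nonpolar_subset(np58)
        params = SasaParams(n_sphere_points=3840)
        base = shrake_rupley(frame, subset, params).total_area
        rot = Rotation.from_euler("zyx", [31.0, -12.0, 57.0], degrees=True)
        moved = Frame(rot.apply(frame.positions) + [1.0, -2.0, 0.5],
                      frame.roles.copy(), frame.box.copy())
        after = shrake_rupley(moved, subset, params).total_area
        assert abs(after - base) / base < 0.001

    def test_kdtree_matches_all_pairs_scan(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(9.0, 11.0, (40, 3))
        frame = carbon_frame(pos)
        params = SasaParams(radii_table=CARBON, n_sphere_points=320)
        mine = shrake_rupley(frame, np.arange(40), params).per_atom_area
        oracle = brute_force_sasa(frame, np.arange(40), params)
        assert np.array_equal(mine, oracle)

    def test_solvent_never_occludes(self):
        # a water placed on top of a carbon must not shadow it
        pos = np.array([[10, 10, 10], [10, 10, 10.01]])
        roles = np.array([int(Role.LIGAND_C_MUS), int(Role.WATER_O)])
        frame = Frame(pos, roles, [20, 20, 20])
        res = shrake_rupley(frame, [0], SasaParams(radii_table={
            Role.LIGAND_C_MUS: 0.2, Role.WATER_O: 0.152}))
        assert res.total_area == pytest.approx(4 * math.pi * 0.34 ** 2,
                                               rel=0.01)

    def test_empty_subset_rejected(self):
        with pytest.raises(ConfigurationError):
            shrake_rupley(carbon_frame([[0, 0, 0]]), [])

    def test_missing_radius_is_config_error(self):
        frame = carbon_frame([[10, 10, 10]])
        with pytest.raises(ConfigurationError):
            shrake_rupley(frame, [0], SasaParams(radii_table={}))


class TestNonpolarSubset:
    def test_published_np_count(self, np58):
        # 29 MUS x 11 + 29 OT x 8 backbone carbons
        assert len(nonpolar_subset(np58)) == 29 * 11 + 29 * 8 == 551

    def test_bare_core_empty(self):
        assert len(nonpolar_subset(nf.build_np(2.0, 0, 0.0, 1))) == 0

    def test_pure_ot_np(self):
        assert len(nonpolar_subset(nf.build_np(2.0, 58, 0.0, 1))) == 58 * 8

    def test_excludes_polar_atoms(self, np58):
        frame = np58.to_frame()
        roles = frame.roles[nonpolar_subset(np58)]
        assert set(roles) <= {int(Role.LIGAND_C_MUS), int(Role.LIGAND_C_OT)}


class TestDeltaSasa:
    def test_identical_frames_zero(self, np58):
        frame = np58.to_frame()
        assert nf.delta_sasa(frame, frame, np58) == pytest.approx(0.0)

    def test_constructed_burial_oracle(self, np58):
        # occluding k isolated-equivalent carbons removes their full area;
        # a phosphate bead placed exactly on a carbon covers it completely
        # (expanded radius 0.32 > 0.31) without touching its neighbors.
        frame = np58.to_frame()
        subset = nonpolar_subset(np58)
        params = SasaParams()
        per_atom = shrake_rupley(frame, subset, params).per_atom_area
        k = 3
        targets = subset[np.argsort(per_atom)[-k:]]  # most exposed carbons
        extra = frame.positions[targets]
        pos = np.vstack([frame.positions, extra])
        roles = np.concatenate([frame.roles,
                                np.full(k, int(Role.PHOSPHATE_P))])
        buried = Frame(pos, roles, frame.box)
        delta = nf.delta_sasa(buried, frame, np58, params)
        expected = -per_atom[np.argsort(per_atom)[-k:]].sum()
        # the occluders may also clip neighboring carbons: delta <= expected
        assert delta <= expected + 1e-9
        assert delta == pytest.approx(expected, rel=0.15)

    def test_burial_never_increases_sasa(self, np58):
        frame = np58.to_frame()
        extra = Frame(np.vstack([frame.positions, [[0.0, 0.0, 0.0]]]),
                      np.concatenate([frame.roles, [int(Role.GOLD)]]),
                      frame.box)
        assert nf.delta_sasa(extra, frame, np58) <= 1e-9

    def test_topology_mismatch_rejected(self, np58):
        frame = np58.to_frame()
        other = Frame(frame.positions[:10], frame.roles[:10], frame.box)
        with pytest.raises(TopologyMismatchError):
            nf.delta_sasa(frame, other, np58)


class TestHydrophobicEnergy:
    @pytest.mark.parametrize("dsasa,expected", [
        (-11.1, -52.17),   # printed as -52.1 +- 2.9
        (-28.3, -133.01),  # printed as approximately -133.0
        (0.0, 0.0),
    ])
    def test_printed_arithmetic(self, dsasa, expected):
        assert nf.hydrophobic_dg(dsasa).dg == pytest.approx(expected,
                                                            abs=0.005)

    def test_additivity(self):
        a, b = -3.7, -7.4
        total = nf.hydrophobic_dg(a + b).dg
        assert total == pytest.approx(nf.hydrophobic_dg(a).dg
                                      + nf.hydrophobic_dg(b).dg, abs=1e-12)

    def test_sign_convention(self):
        assert nf.hydrophobic_dg(-1.0).dg < 0  # burial is favorable
        assert nf.hydrophobic_dg(+1.0).dg > 0


class TestAgainstMdtraj:
    def test_totals_agree_on_random_cluster(self, tmp_path):
        """Independent implementation check: mdtraj's Shrake-Rupley on the
        same coordinates and radii agrees to ~1 % at equal point counts."""
        import mdtraj as md

        from npflip.io import read_gro, write_gro

        rng = np.random.default_rng(3)
        pos = rng.uniform(4.7, 5.3, (30, 3))
        frame = carbon_frame(pos, box=(10.0, 10.0, 10.0))
        path = tmp_path / "cluster.gro"
        write_gro(frame, path)
        traj = md.load(str(path))
        # mdtraj's carbon radius is the Bondi 0.17 nm, matching the default
        ref = md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960,
                               mode="atom").sum()
        mine = shrake_rupley(read_gro(path)[0], np.arange(30)).total_area
        assert mine == pytest.approx(float(ref), rel=0.015)
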