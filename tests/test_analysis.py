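import math

import numpy as np
import pytest

import npflip as nf
from npflip.analysis import (
    DEFAULT_POLAR_THRESHOLDS,
    RDFProfile,
    block_error,
    endgroup_coordination_table,
)
from npflip.core import Frame, Role
from npflip.errors import ConfigurationError, NoMinimumError


def gas_frame(n, box_edge, seed, role=Role.WATER_O):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box_edge, (n, 3))
    return Frame(pos, np.full(n, int(role)), [box_edge] * 3)


def brute_pair_count(pos_a, pos_b, box, threshold, exclude_same_index=False):
    count = 0
    for i, a in enumerate(pos_a):
        for j, b in enumerate(pos_b):
            if exclude_same_index and i == j:
                continue
            disp = a - b
            disp = disp - box * np.round(disp / box)
            if np.linalg.norm(disp) < threshold:
                count += 1
    return count


class TestRDF:
    def test_ideal_gas_is_flat(self):
        frames = [gas_frame(1200, 6.0, s) for s in range(4)]
        prof = nf.rdf(frames, [Role.WATER_O], [Role.WATER_O], 0.1, 2.9)
        sel = prof.bin_centers > 0.5
        assert np.abs(prof.g_values[sel] - 1.0).max() < 0.05

    def test_fixed_separation_occupies_single_bin(self):
        pos = np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.45]])
        roles = np.array([int(Role.SULFONATE_S), int(Role.CHOLINE_N)])
        frame = Frame(pos, roles, [6.0, 6.0, 6.0])
        prof = nf.rdf([frame], [Role.SULFONATE_S], [Role.CHOLINE_N],
                      0.1, 2.0)
        occupied = np.flatnonzero(prof.counts)
        assert len(occupied) == 1
        assert prof.bin_centers[occupied[0]] == pytest.approx(0.45, abs=0.05)

    def test_pair_count_conserved(self):
        frame = gas_frame(300, 6.0, 1)
        prof = nf.rdf([frame], [Role.WATER_O], [Role.WATER_O], 0.1, 2.9)
        brute = brute_pair_count(frame.positions, frame.positions,
                                 frame.box, 2.9, exclude_same_index=True)
        assert prof.counts.sum() == brute

    def test_empty_role_set_rejected(self):
        frame = gas_frame(10, 6.0, 1)
        with pytest.raises(ConfigurationError):
            nf.rdf([frame], [Role.WATER_O], [Role.CHOLINE_N], 0.1, 2.0)

    def test_r_max_beyond_half_box_rejected(self):
        frame = gas_frame(10, 6.0, 1)
        with pytest.raises(ConfigurationError):
            nf.rdf([frame], [Role.WATER_O], [Role.WATER_O], 0.1, 3.5)


class TestFirstMin:
    @staticmethod
    def two_shell_profile(trough=0.70, dr=0.02):
        # equal symmetric shells at 0.45 and 0.95 nm put the trough at 0.70
        r = np.arange(dr / 2, 1.5, dr)
        g = (2.0 * np.exp(-((r - 0.45) / 0.08) ** 2)
             + 2.0 * np.exp(-((r - 0.95) / 0.08) ** 2) + 0.2)
        return RDFProfile(r, g, np.zeros_like(r), dr)

    def test_constructed_trough_recovered(self):
        prof = self.two_shell_profile()
        found = nf.first_min(prof, smooth_window=3)
        assert found == pytest.approx(0.70, abs=prof.dr)

    def test_monotone_profile_has_no_minimum(self):
        r = np.arange(0.01, 1.0, 0.02)
        prof = RDFProfile(r, np.exp(-r), np.zeros_like(r), 0.02)
        with pytest.raises(NoMinimumError):
            nf.first_min(prof)

    def test_smoothing_invariant_on_clean_profile(self):
        prof = self.two_shell_profile()
        assert nf.first_min(prof, 1) == nf.first_min(prof, 3)


class TestContacts:
    def test_no_choline_means_zero(self):
        frame = gas_frame(50, 6.0, 2, role=Role.SULFONATE_S)
        summary = nf.count_contacts([frame])
        assert summary.n_contacts == 0

    def test_constructed_pairs_counted(self):
        # 3 S-N pairs at 0.5 nm, everything else beyond 1 nm
        pos, roles = [], []
        for k in range(3):
            pos += [[1.0 + 2 * k, 1.0, 3.0], [1.0 + 2 * k, 1.5, 3.0]]
            roles += [int(Role.SULFONATE_S), int(Role.CHOLINE_N)]
        pos += [[7.0, 7.0, 7.0]]
        roles += [int(Role.CHOLINE_N)]
        frame = Frame(np.array(pos), np.array(roles), [8.0, 8.0, 8.0])
        summary = nf.count_contacts([frame], threshold=0.7)
        brute = brute_pair_count(
            frame.positions[frame.mask(Role.SULFONATE_S)],
            frame.positions[frame.mask(Role.CHOLINE_N)], frame.box, 0.7)
        assert summary.n_contacts == brute == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        pos = rng.uniform(0, 5.0, (n, 3))
        roles = np.array([int(Role.SULFONATE_S)] * (n // 2)
                         + [int(Role.CHOLINE_N)] * (n - n // 2))
        frame = Frame(pos, roles, [5.0, 5.0, 5.0])
        summary = nf.count_contacts([frame], threshold=0.7)
        brute = brute_pair_count(pos[: n // 2], pos[n // 2:], frame.box, 0.7)
        assert summary.n_contacts == brute

    def test_monotone_in_threshold(self):
        frame = gas_frame(100, 5.0, 3, role=Role.SULFONATE_S)
        frame.roles[50:] = int(Role.CHOLINE_N)
        counts = [nf.count_contacts([frame], t).n_contacts
                  for t in (0.4, 0.7, 1.0)]
        assert counts == sorted(counts)

    def test_invariant_under_rewrap_and_translation(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 5.0, (100, 3))
        roles = np.array([int(Role.SULFONATE_S)] * 50
                         + [int(Role.CHOLINE_N)] * 50)
        frame = Frame(pos, roles, [5.0, 5.0, 5.0])
        base = nf.count_contacts([frame]).n_contacts
        shifted = Frame(np.mod(pos + [1.3, -2.1, 0.8], 5.0), roles,
                        frame.box)
        assert nf.count_contacts([shifted]).n_contacts == base


class TestCoordination:
    def test_isolated_endgroup_is_zero(self, frame29):
        lid = frame29.np_model.mus_ligand_ids()[0]
        # strip all waters: coordination must drop to whatever non-water
        # polar atoms are in range (none, by construction of the generator)
        n_nw = frame29.metadata["n_nonwater"]
        bare = Frame(frame29.positions[:n_nw], frame29.roles[:n_nw],
                     frame29.box, np_model=frame29.np_model,
                     metadata=dict(frame29.metadata))
        rec = nf.coordination([bare], lid)
        assert rec.coordination_mean == 0

    def test_constructed_water_shell_counted(self):
        from .conftest import toy_endgroup_frame

        frame, mid = toy_endgroup_frame([1.0, 1.0, 1.0, 1.0])
        shell = frame.positions[4] + 0.5 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
             [0, 0, 1], [0, 0, -1], [0.7, 0.7, 0]])
        pos = np.vstack([frame.positions, shell])
        roles = np.concatenate([frame.roles,
                                np.full(7, int(Role.WATER_O))])
        f = Frame(pos, roles, frame.box, np_model=frame.np_model)
        rec = nf.coordination([f], 0)
        assert rec.coordination_mean == 7

    def test_hydration_gradient_matches_generator(self):
        p = nf.GeneratorParams(n_plus=20, n_minus=9, seed=6, n_frames=20)
        frames = nf.gen_trajectory(p)
        recs = [nf.coordination(frames, lid)
                for lid in frames[0].np_model.mus_ligand_ids()]
        far = [r.coordination_mean for r in recs if abs(r.dz_mean) > 1.2]
        near = [r.coordination_mean for r in recs if abs(r.dz_mean) < 0.5]
        assert np.mean(far) > np.mean(near)

    def test_missing_threshold_rejected(self, frame29):
        lid = frame29.np_model.mus_ligand_ids()[0]
        with pytest.raises(ConfigurationError):
            nf.coordination([frame29], lid, {Role.WATER_O: 0.7})

    def test_topology_free_table_agrees(self, frame29):
        lid = frame29.np_model.mus_ligand_ids()[0]
        s_idx = frame29.np_model.ligands[lid].endgroup_atoms[0]
        rec = nf.coordination([frame29], lid)
        table = {r.ligand_id: r for r in
                 endgroup_coordination_table([frame29])}
        assert table[s_idx].coordination_mean == rec.coordination_mean


class TestDensityMap:
    def test_uniform_gas_is_flat(self):
        frames = []
        rng = np.random.default_rng(0)
        for _ in range(250):
            pos = rng.uniform(0, 6.0, (2000, 3))
            extra = np.array([[3, 3, 1.0], [3, 3, 5.0],
                              [3.1, 3, 1.0], [3.1, 3, 5.0], [3, 3, 3.0]])
            roles = np.concatenate([np.full(2000, int(Role.LIPID_TAIL)),
                                    [int(Role.PHOSPHATE_P)] * 4,
                                    [int(Role.GOLD)]])
            frames.append(Frame(np.vstack([pos, extra]), roles, [6.0] * 3))
        dmap = nf.density_map(frames, [Role.LIPID_TAIL], 0.5, 0.5,
                              r_max=2.5, z_max=2.5)
        expected = 2000 / 6.0 ** 3
        assert np.abs(dmap.density / expected - 1.0).max() < 0.10

    def test_axis_mass_in_first_radial_bin(self):
        pos = np.array([[3, 3, 3.0]] * 10 + [[3, 3, 1.0], [3, 3, 5.0],
                                             [3.1, 3, 1.0], [3.1, 3, 5.0],
                                             [3, 3, 3.0]])
        roles = np.array([int(Role.WATER_O)] * 10
                         + [int(Role.PHOSPHATE_P)] * 4 + [int(Role.GOLD)])
        frame = Frame(pos, roles, [6.0] * 3)
        dmap = nf.density_map([frame], [Role.WATER_O], 0.5, 0.5,
                              r_max=2.5, z_max=2.5)
        occupied = np.argwhere(dmap.density > 0)
        assert (occupied[:, 0] == 0).all()
        z_centers = 0.5 * (dmap.z_edges[1:] + dmap.z_edges[:-1])
        assert all(abs(z_centers[j]) < 0.5 for _, j in occupied)

    def test_volume_integral_conserves_count(self):
        frame = gas_frame(500, 6.0, 4, role=Role.LIPID_TAIL)
        extra = np.array([[3, 3, 1.0], [3, 3, 5.0], [3.1, 3, 1.0],
                          [3.1, 3, 5.0], [3, 3, 3.0]])
        pos = np.vstack([frame.positions, extra])
        roles = np.concatenate([frame.roles, [int(Role.PHOSPHATE_P)] * 4,
                                [int(Role.GOLD)]])
        f = Frame(pos, roles, frame.box)
        dmap = nf.density_map([f], [Role.LIPID_TAIL], 0.2, 0.2,
                              r_max=3.0, z_max=3.0)
        integral = (dmap.density * dmap.bin_volumes()).sum()
        dxy = f.positions[:500, :2] - [3.0, 3.0]
        dxy -= 6.0 * np.round(dxy / 6.0)
        inside = ((np.hypot(dxy[:, 0], dxy[:, 1]) < 3.0)
                  & (np.abs(f.positions[:500, 2] - 3.0) < 3.0)).sum()
        assert integral == pytest.approx(inside, rel=1e-3)

    def test_zero_width_bins_rejected(self, frame29):
        with pytest.raises(ConfigurationError):
            nf.density_map([frame29], [Role.LIPID_TAIL], 0.0, 0.2)


class TestDepthTrend:
    def test_exact_line_zero_residuals(self):
        pts = [(i, 2.0 - 0.25 * i) for i in range(10)]
        slope, intercept, res = nf.core_depth_trend(pts)
        assert slope == pytest.approx(-0.25)
        assert intercept == pytest.approx(2.0)
        assert np.abs(res).max() < 1e-12

    def test_duplicate_x_still_defined(self):
        slope, intercept, _ = nf.core_depth_trend([(0, 1.0), (0, 2.0),
                                                   (1, 0.0)])
        assert math.isfinite(slope) and math.isfinite(intercept)

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            nf.core_depth_trend([(0, 1.0)])


class TestBlockError:
    def test_iid_gaussian_matches_closed_form(self):
        rng = np.random.default_rng(12)
        sigma, n = 2.0, 4096
        est = block_error(rng.standard_normal(n) * sigma)
        assert est == pytest.approx(sigma / math.sqrt(n), rel=0.20)

    def test_constant_series_zero(self):
        assert block_error(np.full(64, 3.14)) == 0.0

    def test_correlated_series_exceeds_naive(self):
        rng = np.random.default_rng(5)
        n, phi = 8192, 0.9
        y = np.zeros(n)
        e = rng.standard_normal(n)
        for i in range(1, n):
            y[i] = phi * y[i - 1] + e[i]
        naive = y.std(ddof=1) / math.sqrt(n)
        assert block_error(y) > 2 * naive

    def test_short_series_rejected(self):
        with pytest.raises(ConfigurationError):
            block_error([1.0, 2.0, 3.0])
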