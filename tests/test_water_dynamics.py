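"""Hydration-shell RDF, hydrogen bonds, diffusion and rotational relaxation."""

import numpy as np
import pytest

from maostraj.model import Trajectory
from maostraj.synthetic import (
    BrownianSpec,
    ShellSpec,
    gen_brownian,
    gen_hb_telegraph,
    gen_rotational_diffusion,
    gen_shell_waters,
)
from maostraj.water import (
    HBondRecord,
    detect_hbonds,
    detect_hbonds_bruteforce,
    einstein_diffusion,
    find_shells,
    hb_lifetime,
    hb_z_profile,
    proximal_rdf,
    rotational_correlation,
)


# ---------------------------------------------------------------------------
# RDF


class TestProximalRDF:
    def test_uniform_waters_give_unit_rdf(self):
        rng = np.random.default_rng(3)
        box, nw, nf = 30.0, 1000, 1500
        coords = np.zeros((nf, nw + 1, 3))
        coords[:, 0] = box / 2
        coords[:, 1:] = rng.uniform(0, box, size=(nf, nw, 3))
        traj = Trajectory(coords, np.arange(nf, dtype=float), np.array([box] * 3))
        prof = proximal_rdf(traj, np.arange(1, nw + 1), np.array([0]), 0.2, 12.0)
        sel = prof.r_centers >= 2.5
        assert np.all(np.abs(prof.g[sel] - 1.0) < 0.05)

    def test_count_conservation_integral(self):
        spec = ShellSpec((3.75, 8.5), (0.3, 0.3), (0.5, 0.5), 300, 50, 5)
        traj = gen_shell_waters(spec)
        prof = proximal_rdf(traj, np.arange(1, traj.n_atoms), np.array([0]), 0.1, 12.0)
        integral = (prof.g * prof.density * prof.shell_volumes).sum()
        d = np.linalg.norm(traj.coords[:, 1:] - traj.coords[:, :1], axis=2)
        direct = (d <= 12.0).sum() / traj.n_frames
        assert integral == pytest.approx(direct, rel=0.01)

    def test_shell_roundtrip_recovers_construction_radii(self):
        spec = ShellSpec((3.75, 8.5), (0.3, 0.3), (0.5, 0.5), 500, 200, 42)
        traj = gen_shell_waters(spec)
        prof = proximal_rdf(traj, np.arange(1, traj.n_atoms), np.array([0]), 0.1, 12.0)
        maxima = find_shells(prof)
        assert len(maxima) >= 2
        ranked = sorted(maxima, key=lambda m: m[1], reverse=True)
        assert abs(ranked[0][0] - 3.75) < 0.1
        assert abs(ranked[1][0] - 8.5) < 0.15

    def test_multiatom_reference_mc_normalization(self):
        # uniform waters around a 3-atom reference still give g ≈ 1
        rng = np.random.default_rng(8)
        box, nw, nf = 30.0, 800, 400
        coords = np.zeros((nf, nw + 3, 3))
        coords[:, 0] = [12.0, 15.0, 15.0]
        coords[:, 1] = [15.0, 15.0, 15.0]
        coords[:, 2] = [18.0, 15.0, 15.0]
        coords[:, 3:] = rng.uniform(0, box, size=(nf, nw, 3))
        traj = Trajectory(coords, np.arange(nf, dtype=float), np.array([box] * 3))
        prof = proximal_rdf(traj, np.arange(3, nw + 3), np.arange(3), 0.25, 10.0)
        assert prof.normalization == "shell_volume_mc"
        sel = prof.r_centers >= 2.5
        assert np.all(np.abs(prof.g[sel] - 1.0) < 0.08)

    def test_r_max_beyond_half_box_rejected(self):
        traj = gen_shell_waters(ShellSpec((3.0,), (0.2,), (1.0,), 10, 2, 1), box=20.0)
        with pytest.raises(ValueError):
            proximal_rdf(traj, np.arange(1, 11), np.array([0]), 0.1, 15.0)

    def test_empty_selection_rejected(self):
        traj = gen_shell_waters(ShellSpec((3.0,), (0.2,), (1.0,), 10, 2, 1))
        with pytest.raises(ValueError):
            proximal_rdf(traj, np.array([], dtype=int), np.array([0]))


class TestFindShells:
    def test_monotone_profile_has_no_maxima(self):
        from maostraj.water import RDFProfile

        r = np.arange(0.05, 10, 0.1)
        prof = RDFProfile(r, np.exp(-r), "spherical", 1, 1, 0.01, np.ones_like(r))
        assert find_shells(prof) == []

    def test_two_gaussian_profile_recovers_means(self):
        from maostraj.water import RDFProfile

        r = np.arange(0.05, 12, 0.1)
        g = np.exp(-((r - 3.75) ** 2) / 0.18) + 0.4 * np.exp(-((r - 8.5) ** 2) / 0.18)
        prof = RDFProfile(r, g, "spherical", 1, 1, 0.01, np.ones_like(r))
        maxima = find_shells(prof)
        assert len(maxima) == 2
        assert maxima[0][0] == pytest.approx(3.75, abs=0.1)
        assert maxima[1][0] == pytest.approx(8.5, abs=0.1)

    def test_prominence_above_peak_height_empties_list(self):
        from maostraj.water import RDFProfile

        r = np.arange(0.05, 12, 0.1)
        g = np.exp(-((r - 5.0) ** 2) / 0.5)
        prof = RDFProfile(r, g, "spherical", 1, 1, 0.01, np.ones_like(r))
        assert find_shells(prof, min_prominence=5.0) == []


# ---------------------------------------------------------------------------
# hydrogen bonds


def _linear_water_pair(d_oo, angle_deg=0.0):
    """O–H…O geometry with the given O–O distance and H–O–O angle at the donor."""
    a = np.radians(angle_deg)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # donor O
            [0.96 * np.cos(a), 0.96 * np.sin(a), 0.0],  # H
            [d_oo, 0.0, 0.0],  # acceptor O
        ]
    )
    return coords


class TestDetectHbonds:
    def test_linear_geometry_inside_cutoffs_detected(self):
        coords = _linear_water_pair(2.8, 0.0)
        recs = detect_hbonds(coords, [0], [1], [2])
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.8)
        assert recs[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_distance_beyond_cutoff_not_detected(self):
        coords = _linear_water_pair(3.6)
        assert detect_hbonds(coords, [0], [1], [2], d_cut=3.5) == []

    def test_angle_beyond_cutoff_not_detected(self):
        coords = _linear_water_pair(2.8, angle_deg=45.0)
        assert detect_hbonds(coords, [0], [1], [2], angle_cut=30.0) == []

    def test_unbonded_hydrogen_is_hard_error(self):
        coords = _linear_water_pair(2.8)
        coords[1] += 5.0
        with pytest.raises(ValueError, match="not covalently bonded"):
            detect_hbonds(coords, [0], [1], [2])

    @pytest.mark.parametrize("frame_seed", range(10))
    def test_pruned_search_equals_brute_force(self, frame_seed):
        # random periodic water boxes: neighbour-pruned evaluation must equal
        # the all-pairs oracle exactly
        rng = np.random.default_rng(frame_seed)
        box = np.array([14.0, 14.0, 14.0])
        n_wat = 100
        oxy = rng.uniform(0, 14.0, size=(n_wat, 3))
        hvec = rng.normal(size=(n_wat, 3))
        hvec /= np.linalg.norm(hvec, axis=1, keepdims=True)
        coords = np.empty((2 * n_wat, 3))
        coords[0::2] = oxy
        coords[1::2] = oxy + 0.96 * hvec
        donors = np.arange(0, 2 * n_wat, 2)
        hydrogens = np.arange(1, 2 * n_wat, 2)
        acceptors = donors
        fast = detect_hbonds(coords, donors, hydrogens, acceptors, box=box)
        slow = detect_hbonds_bruteforce(coords, donors, hydrogens, acceptors, box=box)
        key = lambda r: (r.donor, r.acceptor)
        assert sorted(map(key, fast)) == sorted(map(key, slow))
        assert len(fast) == len(slow)


class TestHbLifetime:
    def test_all_true_matrix_reports_censored_window(self):
        h = np.ones((5, 100), dtype=bool)
        res = hb_lifetime(h, 0.5, "continuous")
        assert res.censored
        assert res.tau >= 99 * 0.5

    def test_alternating_matrix_gives_tau_dt(self):
        h = np.zeros((3, 100), dtype=bool)
        h[:, ::2] = True
        res = hb_lifetime(h, 0.25, "continuous")
        assert res.tau == pytest.approx(0.25)

    def test_telegraph_recovery_within_5_percent(self):
        tau = 5.0
        h = gen_hb_telegraph(tau, 0.1, 20000, 200, 8)
        res = hb_lifetime(h, 0.1, "continuous")
        expected = 0.1 / (1.0 - np.exp(-0.1 / tau))  # discrete-time mean run
        assert abs(res.tau - tau) / tau < 0.05
        assert abs(res.tau - expected) / expected < 0.02

    def test_continuous_not_above_intermittent_with_reformation(self):
        h = gen_hb_telegraph(5.0, 0.1, 10000, 100, 3)
        cont = hb_lifetime(h, 0.1, "continuous")
        inter = hb_lifetime(h, 0.1, "intermittent")
        assert cont.tau <= inter.tau

    def test_all_false_matrix_rejected(self):
        with pytest.raises(ValueError):
            hb_lifetime(np.zeros((3, 10), dtype=bool), 0.1)


class TestHbZProfile:
    def test_single_slab_when_all_bonds_at_origin(self):
        coords = np.zeros((3, 4, 3))
        recs = [[HBondRecord(f, 0, 1, 2, 2.8, 5.0)] for f in range(3)]
        centers, counts = hb_z_profile(recs, coords, 2.0)
        assert (counts > 0).sum() == 1
        assert counts.sum() == pytest.approx(1.0)  # one bond per frame

    def test_slab_sums_conserve_bond_count(self):
        rng = np.random.default_rng(5)
        nf, nb = 20, 30
        coords = np.zeros((nf, nb, 3))
        coords[:, :, 2] = rng.uniform(-10, 10, size=(nf, nb))
        recs = [
            [HBondRecord(f, b, b, b, 2.8, 5.0) for b in range(nb)] for f in range(nf)
        ]
        _, counts = hb_z_profile(recs, coords, 2.0)
        assert counts.sum() == pytest.approx(nb)

    def test_uniform_bonds_give_flat_profile(self):
        rng = np.random.default_rng(6)
        nf, nb = 200, 50
        coords = np.zeros((nf, nb, 3))
        coords[:, :, 2] = rng.uniform(0, 20, size=(nf, nb))
        recs = [
            [HBondRecord(f, b, b, b, 2.8, 5.0) for b in range(nb)] for f in range(nf)
        ]
        centers, counts = hb_z_profile(recs, coords, 2.0, z_range=(0.0, 20.0))
        expected = nb / len(counts)
        # multinomial fluctuation: s.d. per slab ≈ sqrt(expected / n_frames)
        tol = 4 * np.sqrt(expected / nf)
        assert np.all(np.abs(counts - expected) < tol)


# ---------------------------------------------------------------------------
# diffusion and rotation


class TestEinsteinDiffusion:
    def test_static_particles_have_zero_msd(self):
        coords = np.repeat(np.random.default_rng(1).uniform(0, 10, (1, 8, 3)), 200, axis=0)
        traj = Trajectory(coords, np.arange(200.0), np.array([20.0] * 3))
        res = einstein_diffusion(traj, np.arange(8))
        np.testing.assert_allclose(res.msd, 0.0, atol=1e-9)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_ballistic_motion_flagged_non_diffusive(self):
        t = np.arange(300.0)
        coords = np.zeros((300, 5, 3))
        coords[:, :, 0] = 0.3 * t[:, None]
        traj = Trajectory(coords + 1.0, t, np.array([1e3] * 3))
        res = einstein_diffusion(traj, np.arange(5))
        assert not res.diffusive

    def test_brownian_recovery_within_10_percent(self):
        D = 0.5e-5
        traj = gen_brownian(BrownianSpec(512, D, 1.0, 2000, 60.0, 5))
        res = einstein_diffusion(traj, np.arange(traj.n_atoms))
        assert res.diffusive
        assert abs(res.D - D) / D < 0.10

    def test_invariance_under_global_translation_and_rotation(self):
        from conftest import rotation_z

        traj = gen_brownian(BrownianSpec(64, 0.5e-5, 1.0, 500, 60.0, 6))
        res = einstein_diffusion(traj, np.arange(traj.n_atoms))
        shifted = Trajectory(
            traj.coords, traj.times, traj.box, unwrapped=traj.unwrapped + 7.0
        )
        rotated = Trajectory(
            traj.coords, traj.times, traj.box,
            unwrapped=traj.unwrapped @ rotation_z(30.0).T,
        )
        assert einstein_diffusion(shifted, np.arange(64)).D == pytest.approx(res.D, rel=1e-9)
        assert einstein_diffusion(rotated, np.arange(64)).D == pytest.approx(res.D, rel=1e-9)

    def test_too_few_frames_rejected(self):
        traj = gen_brownian(BrownianSpec(4, 0.5e-5, 1.0, 50, 60.0, 6))
        with pytest.raises(ValueError):
            einstein_diffusion(traj, np.arange(4))


class TestRotationalCorrelation:
    def test_constant_vectors_have_unit_correlation(self):
        v = np.tile(np.array([0.0, 0.0, 1.0]), (50, 10, 1))
        res = rotational_correlation(v, rank=1, dt=1.0)
        np.testing.assert_allclose(res.C, 1.0, atol=1e-12)

    def test_rank1_relaxation_matches_2Dr(self):
        Dr = 0.05
        v = gen_rotational_diffusion(Dr, 0.2, 600, 300, 6)
        res = rotational_correlation(v, rank=1, dt=0.2, max_lag=150)
        assert abs(res.tau - 1.0 / (2 * Dr)) / (1.0 / (2 * Dr)) < 0.10

    def test_rank2_relaxation_matches_6Dr(self):
        Dr = 0.05
        v = gen_rotational_diffusion(Dr, 0.2, 600, 300, 6)
        res = rotational_correlation(v, rank=2, dt=0.2, max_lag=150)
        assert abs(res.tau - 1.0 / (6 * Dr)) / (1.0 / (6 * Dr)) < 0.10

    def test_non_unit_vectors_rejected(self):
        v = np.ones((10, 5, 3))
        with pytest.raises(ValueError):
            rotational_correlation(v)
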