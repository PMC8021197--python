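"""Observables against independent oracles: sorting, closed forms, geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glutensim as g
from glutensim.analysis import _point_to_segments_dist
from glutensim.engine import Box
from glutensim.protocol import Snapshot


def make_snapshot(positions, pairs, kinds=None, lambdas=None, sigmas=None,
                  box=None):
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    n = len(pairs)
    return Snapshot(
        time=0.0, positions=np.asarray(positions, dtype=float),
        box=box or Box(100.0, 100.0, 100.0),
        contact_pairs=pairs,
        contact_kinds=np.asarray(kinds if kinds is not None else [3] * n,
                                 dtype=np.intp),
        contact_lambdas=np.asarray(lambdas if lambdas is not None else [1.0] * n),
        contact_sigmas=np.asarray(sigmas if sigmas is not None else [0.5] * n))


# ---------------------------------------------------------------------------
# contact counting


class TestContactCounts:
    def test_no_contacts_zero_coordination(self):
        snap = make_snapshot(np.zeros((4, 3)), np.empty((0, 2)))
        assert g.coordination_number(snap, 4) == 0.0

    def test_two_beads_one_contact(self):
        snap = make_snapshot([[0, 0, 0], [0.5, 0, 0]], [[0, 1]])
        assert g.coordination_number(snap, 2) == 1.0

    def test_interchain_counting(self):
        chain_ids = np.array([0, 0, 1, 1])
        pos = np.zeros((4, 3))
        snap = make_snapshot(pos, [[0, 1], [1, 2], [2, 3]])
        assert g.interchain_contacts(snap, chain_ids) == 1
        assert g.interchain_contacts(snap, np.zeros(4, dtype=int)) == 0
        assert g.interchain_contacts(snap, chain_ids) <= len(snap.contact_pairs)

    def test_fading_contacts_not_counted(self):
        snap = make_snapshot([[0, 0, 0], [0.5, 0, 0]], [[0, 1]], lambdas=[0.0])
        assert g.coordination_number(snap, 2) == 0.0

    def test_static_contacts_gated_by_distance(self):
        from glutensim.forcefield import KIND_STATIC
        pos = [[0, 0, 0], [2.0, 0, 0]]
        snap = make_snapshot(pos, [[0, 1]], kinds=[KIND_STATIC], sigmas=[0.55])
        assert g.coordination_number(snap, 2) == 0.0       # 2.0 > 1.5 * 0.55
        snap.positions[1, 0] = 0.6
        assert g.coordination_number(snap, 2) == 1.0


# ---------------------------------------------------------------------------
# RMSF


class TestRmsf:
    def test_frozen_trajectory_zero(self):
        frames = np.tile(np.arange(12.0).reshape(4, 3), (5, 1, 1))
        per_res, mean = g.rmsf(frames, remove_drift=False)
        np.testing.assert_allclose(per_res, 0.0)
        assert mean == 0.0

    def test_alternating_bead_closed_form(self):
        a = 0.7
        frames = np.zeros((10, 1, 3))
        frames[::2, 0, 0] = a
        frames[1::2, 0, 0] = -a
        per_res, _ = g.rmsf(frames, remove_drift=False)
        assert per_res[0] == pytest.approx(a)

    def test_rigid_translation_removed_with_drift_correction(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 8, 3))
        drift = np.cumsum(rng.normal(size=(6, 1, 3)), axis=0)
        _, m0 = g.rmsf(base, remove_drift=True)
        _, m1 = g.rmsf(base + drift, remove_drift=True)
        assert m1 == pytest.approx(m0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            g.rmsf(np.zeros((1, 4, 3)))


# ---------------------------------------------------------------------------
# shape / distortion


class TestDistortion:
    def test_spherical_shell_is_sphere_like(self):
        fix = g.make_geometry_fixture("shell")
        assert g.distortion(fix.chains[0]).w == pytest.approx(0.0, abs=0.02)

    def test_line_is_rod_like(self):
        pts = np.stack([np.linspace(0, 10, 50), np.zeros(50), np.zeros(50)],
                       axis=1)
        pts[:, 1] += 1e-6 * np.arange(50)  # break exact degeneracy
        assert g.distortion(pts).w == pytest.approx(1.0, abs=1e-3)

    def test_matches_explicit_inertia_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 3)) * [2.0, 1.0, 0.5]
        shape = g.distortion(pts)
        # independent loop-built inertia tensor
        c = pts.mean(axis=0)
        inertia = np.zeros((3, 3))
        for p in pts - c:
            inertia += np.dot(p, p) * np.eye(3) - np.outer(p, p)
        radii = np.sqrt(np.sort(np.linalg.eigvalsh(inertia)) / len(pts))
        assert (shape.R1, shape.R2, shape.R3) == pytest.approx(tuple(radii))
        assert -1.0 <= shape.w <= 1.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            g.distortion(np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# F_max / W_max


class TestFmax:
    def test_sort_oracle_on_small_series(self):
        mean, sd = g.fmax(np.array([1.0, 2, 3, 4, 5, 6, 7]))
        top5 = np.sort([1.0, 2, 3, 4, 5, 6, 7])[-5:]
        assert mean == pytest.approx(top5.mean()) == 5.0
        assert sd == pytest.approx(top5.std())

    def test_constant_series(self):
        mean, sd = g.fmax(np.full(10, 2.5))
        assert (mean, sd) == (2.5, 0.0)

    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=30),
           st.floats(0.1, 10.0))
    def test_permutation_invariant_and_scale_equivariant(self, values, c):
        arr = np.asarray(values)
        rng = np.random.default_rng(0)
        m1, _ = g.fmax(arr)
        m2, _ = g.fmax(rng.permutation(arr))
        assert m1 == pytest.approx(m2)
        m3, _ = g.fmax(c * arr)
        assert m3 == pytest.approx(c * m1, rel=1e-9, abs=1e-9)

    def test_min_separation_skips_neighbouring_spikes(self):
        series = np.zeros(50)
        series[10:13] = [9.0, 10.0, 9.5]
        series[30] = 1.0
        mean, _ = g.fmax(series, n_points=2, min_separation=5)
        assert mean == pytest.approx((10.0 + 1.0) / 2)

    def test_series_too_short(self):
        with pytest.raises(ValueError):
            g.fmax(np.ones(3))

    def test_weighted_combination(self):
        # equal standard errors -> plain average
        m, _ = g.weighted_fmax([(2.0, 0.5), (4.0, 0.5)])
        assert m == pytest.approx(3.0)
        # a 2x larger SE gets a 4x smaller weight
        m, _ = g.weighted_fmax([(2.0, 0.5), (4.0, 1.0)])
        assert m == pytest.approx((2.0 * 4 + 4.0 * 1) / 5)


class TestWmax:
    def test_monotone_work_final_value(self):
        w = np.linspace(0, 5, 20)
        assert g.wmax(w) == 5.0

    def test_rupture_plateau(self):
        ramp = g.make_ramp_force("rupture")
        from scipy.integrate import cumulative_trapezoid
        work = np.concatenate([[0.0], cumulative_trapezoid(ramp["force"],
                                                           ramp["s"])])
        # independent fine-grid quadrature of the same rupture profile
        s_fine = np.linspace(0, 10, 20001)
        f_fine = np.where(s_fine < 4.0, 2.0, 0.0)
        w_ref = np.trapezoid(f_fine, s_fine)
        assert g.wmax(work) == pytest.approx(w_ref, rel=1e-2)
        assert g.wmax(work) >= 0.0


# ---------------------------------------------------------------------------
# dynamic modulus fit


class TestModulusFit:
    def run_fit(self, planted, surface=10.0, s0=4.0):
        return g.fit_dynamic_modulus(
            planted["t"], planted["strain"], planted["force"],
            surface_area=surface, s0=s0, amplitude=planted["amplitude"],
            omega=planted["omega"])

    def test_noiseless_recovery_exact(self):
        d = g.make_planted_rheology(F0=0.7, delta=0.6, omega=0.2)
        fit = self.run_fit(d)
        assert fit.delta == pytest.approx(0.6, abs=1e-9)
        assert fit.F0_nN == pytest.approx(g.units.force_to_nN(0.7), rel=1e-9)

    def test_pure_elastic_zero_loss(self):
        d = g.make_planted_rheology(F0=1.0, delta=0.0, omega=0.3)
        fit = self.run_fit(d)
        assert fit.Gpp_MPa == pytest.approx(0.0, abs=1e-9)
        assert fit.tan_delta == pytest.approx(0.0, abs=1e-9)

    def test_pure_viscous_infinite_tan_delta(self):
        d = g.make_planted_rheology(F0=1.0, delta=np.pi / 2, omega=0.3)
        fit = self.run_fit(d)
        assert fit.Gp_MPa == pytest.approx(0.0, abs=1e-9)
        assert np.isinf(fit.tan_delta)

    @pytest.mark.parametrize("delta", [0.0, np.pi / 4, np.pi / 2])
    def test_recovery_across_phases_at_snr_5(self, delta):
        F0 = 1.0
        errs = []
        for seed in range(40):
            d = g.make_planted_rheology(F0=F0, delta=delta, omega=0.2,
                                        noise_sd=F0 / 5.0, seed=seed)
            fit = self.run_fit(d)
            errs.append(fit.delta - delta)
        errs = np.asarray(errs)
        # delta folding reflects errors at the interval edges; compare folded
        errs = np.minimum(np.abs(errs), np.pi - np.abs(errs))
        se = errs.std(ddof=1) / np.sqrt(len(errs))
        assert np.abs(errs).mean() < 5 * se + 0.05

    def test_monte_carlo_recovery_within_three_se(self):
        F0, delta = 0.7, 0.6
        deltas, f0s = [], []
        for seed in range(100):
            d = g.make_planted_rheology(F0=F0, delta=delta, omega=0.15,
                                        noise_sd=F0 / 10.0, seed=seed)
            fit = self.run_fit(d)
            deltas.append(fit.delta)
            f0s.append(fit.F0_nN)
        se_d = np.std(deltas, ddof=1) / 10.0
        se_f = np.std(f0s, ddof=1) / 10.0
        assert abs(np.mean(deltas) - delta) < 3 * se_d
        assert abs(np.mean(f0s) - g.units.force_to_nN(F0)) < 3 * se_f

    @given(st.floats(0.05, np.pi - 0.05))
    def test_pythagoras_identity_of_moduli(self, delta):
        d = g.make_planted_rheology(F0=0.9, delta=delta, omega=0.2)
        fit = self.run_fit(d)
        ratio = fit.phi0_MPa / fit.gamma0
        assert fit.Gp_MPa ** 2 + fit.Gpp_MPa ** 2 == pytest.approx(ratio ** 2,
                                                                   rel=1e-9)

    def test_needs_a_full_period_after_discard(self):
        d = g.make_planted_rheology(F0=1.0, delta=0.3, omega=0.2, n_periods=2)
        with pytest.raises(ValueError):
            g.fit_dynamic_modulus(d["t"], d["strain"], d["force"], 10.0, 4.0,
                                  d["amplitude"], d["omega"],
                                  discard_periods=1.5)


# ---------------------------------------------------------------------------
# entanglements


def gauss_linking_number(curve1, curve2):
    """Discrete Gauss double integral over two closed polylines (oracle)."""
    r1 = np.asarray(curve1)
    r2 = np.asarray(curve2)
    d1 = np.diff(r1, axis=0)
    d2 = np.diff(r2, axis=0)
    m1 = 0.5 * (r1[:-1] + r1[1:])
    m2 = 0.5 * (r2[:-1] + r2[1:])
    total = 0.0
    for a, da in zip(m1, d1):
        rv = a - m2
        norm = np.linalg.norm(rv, axis=1) ** 3
        total += np.sum(np.einsum("ij,ij->i", np.cross(da, d2), rv) / norm)
    return total / (4 * np.pi)


def close_below(curve, depth=-12.0):
    """Close an open curve through a large detour far below the scene."""
    a, b = curve[0], curve[-1]
    detour = np.array([[b[0], b[1], depth], [a[0], a[1], depth]])
    return np.concatenate([curve, detour, curve[:1]])


class TestEntanglements:
    def test_straight_pair_zero(self):
        fix = g.make_geometry_fixture("straight_pair")
        res = g.entanglement_count(fix.chains)
        assert res.l_k == fix.oracle["l_k"] == 0
        assert res.converged

    def test_hook_pair_one(self):
        fix = g.make_geometry_fixture("hook_pair")
        res = g.entanglement_count(fix.chains)
        assert res.l_k == fix.oracle["l_k"] == 1

    def test_counts_invariant_under_rigid_rotation(self):
        fix = g.make_geometry_fixture("hook_pair")
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rotated = [c @ R.T for c in fix.chains]
        assert g.entanglement_count(rotated).l_k == 1

    @pytest.mark.parametrize("kind,link", [("straight_pair", 0),
                                           ("hook_pair", 1)])
    def test_agreement_with_gauss_linking_oracle(self, kind, link):
        # close both open curves through distant detours; the hook then has
        # |linking number| 1 and the straight pair 0
        fix = g.make_geometry_fixture(kind)
        c1, c2 = fix.chains
        lk = gauss_linking_number(close_below(c1, -20.0), close_below(c2, -30.0))
        assert round(abs(lk)) == link

    def test_three_chain_fixture(self):
        fix = g.make_geometry_fixture("hook_pair")
        bystander = np.stack([np.full(11, -8.0), np.linspace(-5, 5, 11),
                              np.zeros(11)], axis=1)
        res = g.entanglement_count(fix.chains + [bystander])
        assert res.l_k == 1


# ---------------------------------------------------------------------------
# cavities


class TestCavities:
    def test_dense_cluster_has_no_cavities(self):
        x = np.arange(1.0, 3.1, 0.4)
        pts = np.array(np.meshgrid(x, x, x)).reshape(3, -1).T
        res = g.cavity_volumes(pts, Box(4.0, 4.0, 4.0))
        assert res.n_cavities == 0

    def test_shell_volume_within_15_percent(self):
        fix = g.make_geometry_fixture("shell")
        res = g.cavity_volumes(fix.chains[0], fix.box,
                               probe=fix.oracle["probe"])
        assert res.n_cavities == 1
        assert res.max_volume == pytest.approx(fix.oracle["volume"], rel=0.15)

    def test_divider_splits_cavity(self):
        whole = g.make_geometry_fixture("shell_box")
        split = g.make_geometry_fixture("shell_box_divided")
        r1 = g.cavity_volumes(whole.chains[0], whole.box)
        r2 = g.cavity_volumes(split.chains[0], split.box)
        assert r1.n_cavities == 1
        assert r2.n_cavities == r1.n_cavities + 1
        # splitting loses a wall-slab of volume but roughly conserves it
        assert r2.total_cavity_volume < r1.total_cavity_volume

    def test_volume_partition_is_exact_on_the_grid(self):
        fix = g.make_geometry_fixture("shell")
        res = g.cavity_volumes(fix.chains[0], fix.box)
        total = (res.occupied_volume + res.exterior_volume
                 + res.total_cavity_volume)
        assert total == pytest.approx(res.box_volume, abs=1e-9)
        assert res.box_volume == pytest.approx(fix.box.volume, rel=1e-12)

    def test_grid_coarser_than_probe_rejected(self):
        with pytest.raises(ValueError):
            g.cavity_volumes(np.zeros((1, 3)), Box(2, 2, 2), grid=0.5,
                             probe=0.38)


# ---------------------------------------------------------------------------
# kneading-effect ratios


class TestOscillationRatios:
    def test_identical_inputs_give_unit_ratios(self):
        obs = {"l_k": (3.0, 0.5), "F_max": (1.2, 0.1)}
        out = g.oscillation_effect_ratios(obs, obs)
        for r, _ in out.values():
            assert r == pytest.approx(1.0)

    def test_doubled_numerator(self):
        out = g.oscillation_effect_ratios({"F_max": (2.4, 0.0)},
                                          {"F_max": (1.2, 0.0)})
        assert out["F_max"] == (2.0, 0.0)

    def test_error_propagation_matches_resampling(self):
        rng = np.random.default_rng(8)
        va, ea, vb, eb = 3.0, 0.2, 2.0, 0.15
        _, err = g.oscillation_effect_ratios({"x": (va, ea)},
                                             {"x": (vb, eb)})["x"]
        samples = rng.normal(va, ea, 200_000) / rng.normal(vb, eb, 200_000)
        assert err == pytest.approx(samples.std(), rel=0.05)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            g.oscillation_effect_ratios({"x": (1.0, 0.1)}, {"x": (0.0, 0.1)})


def test_point_to_segment_distance_helper():
    p = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    q = np.array([[1.0, 0, 0], [1.0, 1.0, 0]])
    # nearest approach is the shared endpoint (1, 1, 0) of the second segment
    assert _point_to_segments_dist(np.array([0.5, 1.0, 0.0]), p, q) \
        == pytest.approx(0.5)
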