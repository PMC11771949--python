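"""Feasibility conditions, Lambert-W extrema and hierarchical bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dorsalhorn.circuits import simple_circuit, static_circuit
from dorsalhorn.constraints import (
    LambertSubproblem,
    analytic_bounds,
    analytic_member,
    check_feasible,
    check_feasible_batch,
    extremize_over_stimulus,
    lambert_extrema,
    normalize,
    presample_hierarchical,
)


def _grid_extremum(obj, interval, mode, n=100_001):
    f = np.linspace(interval[0], interval[1], n)
    v = np.asarray(obj(f))
    return float(v.min() if mode == "min" else v.max())


class TestFeasibilityOracle:
    def test_zero_inhibitory_drive_is_infeasible(self, simple_spec):
        res = check_feasible(simple_spec,
                             {"g_AbI": 0.0, "g_IE": 1.0, "g_AbE": 4.0})
        assert not res.ok
        assert "I fires" in res.violated

    def test_oracle_verified_feasible_point(self, simple_spec):
        # interior point of the analytically computed coupling intervals
        assert check_feasible(simple_spec,
                              {"g_AbI": 4.0, "g_IE": 1.0, "g_AbE": 3.8}).ok

    def test_excess_abeta_drive_breaks_ablation_ceiling(self, simple_spec):
        """g_AbE > (V_E,max - V_E,rest)/f_max = 6.89 violates the I-ablation
        upper bound regardless of the other couplings."""
        res = check_feasible(simple_spec,
                             {"g_AbI": 4.0, "g_IE": 1.0, "g_AbE": 6.95})
        assert not res.ok
        assert "E upper bound (I abl)" in res.violated

    def test_batch_oracle_agrees_with_scalar(self, simple_spec):
        rng = np.random.default_rng(0)
        G = np.c_[rng.uniform(2, 7, 60), rng.uniform(0.2, 2.5, 60),
                  rng.uniform(2, 7, 60)]
        batch = check_feasible_batch(simple_spec, G)
        scalar = np.array([
            check_feasible(simple_spec, simple_spec.coupling_dict(g)).ok
            for g in G
        ])
        np.testing.assert_array_equal(batch, scalar)

    def test_grid_floor_enforced(self, simple_spec):
        with pytest.raises(ValueError):
            check_feasible(simple_spec,
                           {"g_AbI": 4.0, "g_IE": 1.0, "g_AbE": 3.8},
                           n_grid=10)


class TestLambert:
    @pytest.mark.parametrize("seed", range(4))
    def test_rate_over_f_matches_dense_grid(self, seed):
        """Closed-form extrema of g_IE f_I / f agree with a 1e5-point grid
        to 1e-6 relative, across random feasible coupling pairs."""
        rng = np.random.default_rng(seed)
        for _ in range(25):
            g_ai = rng.uniform(2.07, 7.08)
            g_ie = rng.uniform(0.3, 2.5)
            sub = LambertSubproblem(g_ai, g_ie, 0.0, (10.0, 20.0))
            crit = lambert_extrema(sub)
            val, _ = extremize_over_stimulus(sub.objective, sub.interval,
                                             "min", criticals=crit)
            ref = _grid_extremum(sub.objective, sub.interval, "min")
            assert val == pytest.approx(ref, rel=1e-6)

    @pytest.mark.parametrize("mode,K", [("min", -35.1), ("max", -137.8)])
    def test_ablation_row_family_matches_dense_grid(self, mode, K):
        """The affine-over-rate family (ablation rows) has opposite-sign
        constants for the fires and ceiling rows; both match the grid."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            g_a = rng.uniform(2.07, 7.08)
            g_ae = rng.uniform(3.6, 10.0)
            sub = LambertSubproblem(g_a, g_ae, K, (10.0, 20.0),
                                    kind="affine_over_rate")
            crit = lambert_extrema(sub)
            val, _ = extremize_over_stimulus(sub.objective, sub.interval,
                                             mode, criticals=crit)
            ref = _grid_extremum(sub.objective, sub.interval, mode)
            assert val == pytest.approx(ref, rel=1e-6)

    def test_critical_points_are_stationary(self):
        sub = LambertSubproblem(2.5, 1.0, 0.0, (1.0, 40.0))
        crit = lambert_extrema(sub)
        assert crit  # both branches land inside this wide interval
        for f in crit:
            h = 1e-5
            d = (sub.objective(np.array([f + h]))[0]
                 - sub.objective(np.array([f - h]))[0]) / (2 * h)
            assert abs(d) < 1e-6

    def test_closed_form_requires_zero_offset(self):
        sub = LambertSubproblem(2.5, 1.0, 35.1, (10.0, 20.0))
        with pytest.raises(ValueError):
            lambert_extrema(sub)

    def test_empty_result_when_roots_outside_interval(self):
        sub = LambertSubproblem(2.5, 1.0, 0.0, (10.0, 12.0))
        for f in lambert_extrema(sub):
            assert 10.0 < f < 12.0


class TestExtremize:
    def test_constant_objective_left_endpoint(self):
        val, arg = extremize_over_stimulus(
            lambda f: np.full_like(np.asarray(f, float), 2.5),
            (10.0, 20.0), "min")
        assert val == pytest.approx(2.5)
        assert arg == pytest.approx(10.0)

    def test_numeric_refinement_matches_grid(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g_ai = rng.uniform(2.07, 7.08)
            g_ie = rng.uniform(0.3, 2.5)
            C = rng.uniform(-60, 60)
            def obj(f, a=g_ai, g=g_ie, c=C):
                f = np.asarray(f, float)
                r = 40 * (1 + np.tanh((-60 + a * f + 30) / 9.3))
                return (g * r + c) / f
            for mode in ("min", "max"):
                val, _ = extremize_over_stimulus(obj, (10.0, 20.0), mode)
                assert val == pytest.approx(
                    _grid_extremum(obj, (10.0, 20.0), mode), rel=1e-6)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            extremize_over_stimulus(lambda f: f, (20.0, 10.0), "min")


class TestHierarchicalBounds:
    def test_first_interval_is_analytic(self, simple_spec):
        """g_AbI in [(V_thr - V_rest)/f_min, (V_max - V_rest)/f_max]."""
        name, iv = analytic_bounds(simple_spec, {})
        assert name == "g_AbI"
        assert iv[0] == pytest.approx(20.7 / 10)
        assert iv[1] == pytest.approx(141.6 / 20)

    def test_out_of_order_assignment_rejected(self, simple_spec):
        with pytest.raises(ValueError):
            analytic_bounds(simple_spec, {"g_IE": 1.0})

    def test_membership_agrees_with_oracle(self, simple_spec, simple_aps):
        """Hierarchical-interval membership equals the brute-force oracle on
        feasible points and box-random probes (boundary cases excepted)."""
        pts, box = simple_aps
        rng = np.random.default_rng(4)
        probes = box.lo + rng.uniform(size=(50, 3)) * (box.hi - box.lo)
        cases = np.vstack([pts[:50], probes])
        agree = 0
        for g in cases:
            m = analytic_member(simple_spec, g)
            o = check_feasible(simple_spec, simple_spec.coupling_dict(g),
                               n_grid=1000).ok
            agree += m == o
        assert agree >= 99

    def test_static_membership_agrees_with_oracle(self, static_spec):
        pts, box = presample_hierarchical(static_spec, 1000, seed=5)
        rng = np.random.default_rng(6)
        probes = box.lo + rng.uniform(size=(15, 5)) * (box.hi - box.lo)
        cases = np.vstack([pts[:15], probes])
        agree = sum(
            analytic_member(static_spec, g)
            == check_feasible(static_spec, static_spec.coupling_dict(g),
                              n_grid=500).ok
            for g in cases
        )
        assert agree >= len(cases) - 1


class TestPresample:
    def test_all_points_feasible(self, simple_spec, simple_aps):
        pts, _ = simple_aps
        assert check_feasible_batch(simple_spec, pts).all()

    def test_minimum_size_enforced(self, simple_spec):
        with pytest.raises(ValueError):
            presample_hierarchical(simple_spec, 100, seed=0)

    def test_box_tracks_analytic_interval(self, simple_spec, simple_aps):
        """The box stays inside the level-1 interval; its upper edge
        approaches the analytic 7.08 while the conditional constraints keep
        the lower edge above the unconditional 2.07."""
        _, box = simple_aps
        _, iv = analytic_bounds(simple_spec, {})
        assert iv[0] - 1e-9 <= box.lo[0] and box.hi[0] <= iv[1] + 1e-9
        assert box.hi[0] == pytest.approx(iv[1], rel=0.02)
        assert 2.07 <= box.lo[0] <= 3.0

    def test_deterministic_given_seed(self, simple_spec):
        a, _ = presample_hierarchical(simple_spec, 1000, seed=3)
        b, _ = presample_hierarchical(simple_spec, 1000, seed=3)
        np.testing.assert_array_equal(a, b)


class TestNormalization:
    @settings(max_examples=200, deadline=None)
    @given(u=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3))
    def test_round_trip_identity(self, simple_aps, u):
        _, box = simple_aps
        g = box.lo + np.array(u) * (box.hi - box.lo)
        back = normalize(normalize(g, box), box, inverse=True)
        np.testing.assert_allclose(back, g, rtol=0, atol=1e-12)

    def test_box_corners_map_to_unit_corners(self, simple_aps):
        _, box = simple_aps
        np.testing.assert_allclose(normalize(box.lo, box), 0.0, atol=1e-15)
        np.testing.assert_allclose(normalize(box.hi, box), 1.0, atol=1e-15)

    def test_degenerate_box_rejected(self, simple_aps):
        from dorsalhorn.constraints import NormalizationBox
        _, box = simple_aps
        with pytest.raises(ValueError):
            NormalizationBox(box.names, box.lo, box.lo.copy(), 10, 0)


class TestStructuralProperties:
    def test_more_excitation_never_restores_pain_inhibition(self, simple_spec):
        """If pain inhibition is violated, increasing g_AbE keeps it
        violated (the condition is monotone in the excitatory drive)."""
        g = {"g_AbI": 4.0, "g_IE": 0.5, "g_AbE": 5.0}
        assert "pain inhibition" in check_feasible(simple_spec, g).violated
        for bump in (0.5, 1.0, 3.0):
            g2 = dict(g, g_AbE=g["g_AbE"] + bump)
            assert "pain inhibition" in check_feasible(simple_spec, g2).violated

    def test_aps_correlation_structure(self, simple_pipeline):
        """Balanced excitation/inhibition on E: corr(g_IE, g_AbE) > 0;
        multi-synaptic compensation: corr(g_IE, g_AbI) < 0."""
        names = list(simple_pipeline.report.names)
        corr = simple_pipeline.report.correlation
        i_ie, i_ae, i_ai = (names.index(n) for n in ("g_IE", "g_AbE", "g_AbI"))
        assert corr[i_ie, i_ae] > 0
        assert corr[i_ie, i_ai] < 0
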