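import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adtime import GroupCurveParams, gen_cognitive_cohort, predict_shifted, spearman
from adtime.ctime import (
    CTimeAligner,
    CTimeConfig,
    anchor_ctime,
    baseline_anchor,
    fit_group_curve,
    fit_shift,
    hinge_scan,
    optimize_ctime,
    _shift_sse_grid,
    _split_subjects,
)
from adtime.exceptions import InputDataError, UnidentifiableShiftError
from tests.conftest import make_long


# ---------------------------------------------------------------------------
# baseline anchoring


class TestBaselineAnchor:
    def test_subtracts_baseline(self):
        df = make_long([("a", 70, 0.0, 1.2, "c"), ("a", 71, 1.0, 1.0, "c"),
                        ("a", 72, 2.0, 0.5, "c")])
        out = baseline_anchor(df)
        np.testing.assert_allclose(out["value"], [0.0, -0.2, -0.7])

    def test_idempotent_on_anchored_input(self):
        df = make_long([("a", 70, 0.0, 0.0, "c"), ("a", 71, 1.0, -0.3, "c")])
        out = baseline_anchor(df)
        np.testing.assert_allclose(out["value"], df["value"])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8), st.integers(0, 10**6))
    def test_anchor_twice_equals_anchor_once(self, values, salt):
        df = make_long(
            [(f"s{salt}", 70 + j, float(j), v, "c") for j, v in enumerate(values)]
        )
        once = baseline_anchor(df)
        twice = baseline_anchor(once)
        np.testing.assert_allclose(twice["value"], once["value"])

    def test_empty_rejected(self):
        with pytest.raises(InputDataError):
            baseline_anchor(make_long([]))


# ---------------------------------------------------------------------------
# shift fitting


class TestFitShift:
    def test_noiseless_self_consistency(self, default_curve):
        t = np.array([0.0, 1.5, 3.0, 5.0, 7.0])
        y = predict_shifted(default_curve, -4.0, t)
        est = fit_shift((t, y), default_curve)
        assert est.delta == pytest.approx(-4.0, abs=1e-3)
        assert est.sse < 1e-10

    def test_linear_curve_unidentifiable(self):
        theta = GroupCurveParams(-0.2, 0.0, 0.0, 0.3)
        with pytest.raises(UnidentifiableShiftError):
            fit_shift((np.array([0.0, 1.0]), np.array([0.0, -0.2])), theta)

    def test_matches_exhaustive_grid_oracle(self, default_curve, rng):
        """NLS shift equals a brute-force 0.01-year grid within 0.02 years."""
        bounds = (-20.0, 8.0)
        grid = np.arange(bounds[0], bounds[1] + 0.005, 0.01)
        for _ in range(20):
            true_d = rng.uniform(-14, 4)
            t = np.sort(np.r_[0.0, rng.uniform(0.5, 10, 5)])
            y = predict_shifted(default_curve, true_d, t) + rng.normal(0, 0.1, t.size)
            est = fit_shift((t, y), default_curve, bounds=bounds)
            oracle = grid[int(np.argmin(_shift_sse_grid(default_curve, t, y, grid)))]
            assert abs(est.delta - oracle) <= 0.02

    def test_single_observation_flagged_low_information(self, default_curve):
        est = fit_shift((np.array([0.0]), np.array([0.0])), default_curve)
        assert est.low_information


# ---------------------------------------------------------------------------
# group curve refits


class TestFitGroupCurve:
    def test_noise_free_recovery_with_true_shifts(self, default_curve):
        cohort, truth = gen_cognitive_cohort(50, noise_sd=0.0, seed=21)
        subjects = _split_subjects(baseline_anchor(cohort))
        deltas = truth.subjects.set_index("subject_id")["delta"].to_dict()
        theta = fit_group_curve(
            subjects, deltas, GroupCurveParams(-0.05, -0.001, -0.01, 0.3)
        )
        np.testing.assert_allclose(
            theta.as_array(), default_curve.as_array(), rtol=0.05, atol=5e-3
        )

    def test_all_zero_data_gives_flat_curve(self):
        t = np.linspace(0, 8, 5)
        subjects = [("a", t, np.zeros(5)), ("b", t, np.zeros(5))]
        theta = fit_group_curve(
            subjects, {"a": 0.0, "b": 0.0}, GroupCurveParams(-0.1, -0.01, -0.01, 0.3)
        )
        from adtime import group_curve_eval

        np.testing.assert_allclose(
            group_curve_eval(theta, np.linspace(0, 8, 20)), 0.0, atol=1e-6
        )

    def test_fit_beats_truth_in_sample(self, default_curve):
        cohort, truth = gen_cognitive_cohort(40, noise_sd=0.1, seed=22)
        subjects = _split_subjects(baseline_anchor(cohort))
        deltas = truth.subjects.set_index("subject_id")["delta"].to_dict()
        theta = fit_group_curve(subjects, deltas, default_curve)

        def sse(th):
            return sum(
                float(np.sum((y - predict_shifted(th, deltas[s], t)) ** 2))
                for s, t, y in subjects
            )

        assert sse(theta) <= sse(default_curve) + 1e-9


# ---------------------------------------------------------------------------
# alternating optimization


class TestOptimizeCtime:
    def test_recovery_and_monotone_trace(self, small_cognitive_cohort):
        cohort, truth = small_cognitive_cohort
        res = optimize_ctime(cohort, CTimeConfig(max_iter=200))
        trace = np.asarray(res.trace)
        assert np.all(np.diff(trace) <= 1e-9)
        merged = res.shifts.merge(truth.subjects, on="subject_id")
        rho, _ = spearman(merged["delta_x"], merged["delta_y"])
        assert rho >= 0.9

    def test_noise_free_perfect_fit(self):
        cohort, _ = gen_cognitive_cohort(25, noise_sd=0.0, seed=5)
        res = optimize_ctime(cohort, CTimeConfig(tol=1e-6, max_iter=500))
        assert res.trace[-1] / len(cohort) < 1e-6

    def test_converged_state_is_fixed_point(self, small_cognitive_cohort):
        cohort, _ = small_cognitive_cohort
        cfg = CTimeConfig(max_iter=300)
        res = optimize_ctime(cohort, cfg)
        assert res.converged
        res2 = optimize_ctime(cohort, CTimeConfig(theta_init=res.theta, max_iter=300))
        rel = np.abs(res2.theta.as_array() - res.theta.as_array()) / np.maximum(
            1.0, np.abs(res.theta.as_array())
        )
        assert res2.n_iter <= 3
        assert float(rel.max()) < 5e-4

    def test_translation_gauge_rank_invariance(self):
        """Shifting all true positions by a constant must not change the
        recovered ordering (the gauge is pinned by recentring)."""
        base = dict(n_subjects=40, noise_sd=0.02, seed=31)
        c1, t1 = gen_cognitive_cohort(
            shift_dist={"dist": "uniform", "low": -10.0, "high": 0.0}, **base
        )
        c2, t2 = gen_cognitive_cohort(
            shift_dist={"dist": "uniform", "low": -7.0, "high": 3.0}, **base
        )
        # same seed: second cohort's shifts are the first's plus 3 years
        np.testing.assert_allclose(
            t2.subjects["delta"], t1.subjects["delta"] + 3.0, atol=1e-12
        )
        cfg = CTimeConfig(max_iter=80)
        r1 = optimize_ctime(c1, cfg)
        r2 = optimize_ctime(c2, cfg)
        rho, _ = spearman(r1.shifts["delta"], r2.shifts["delta"])
        assert rho > 0.999

    def test_min_visits_exclusion_counted(self):
        cohort, _ = gen_cognitive_cohort(20, noise_sd=0.05, seed=41)
        short = make_long([("x9999", 70, 0.0, 0.0, "cognition"),
                           ("x9999", 71, 1.0, -0.1, "cognition")])
        res = optimize_ctime(
            pd.concat([cohort, short], ignore_index=True), CTimeConfig(max_iter=30)
        )
        assert res.n_excluded == 1
        assert "x9999" not in set(res.shifts["subject_id"])


# ---------------------------------------------------------------------------
# hinge scan and anchoring


class TestHinge:
    @staticmethod
    def _piecewise_cohort(n, hstar, post_slope, noise, seed, span=(-2.5, 2.5)):
        rng = np.random.default_rng(seed)
        ct = rng.uniform(span[0], span[1], n)
        rows = []
        for i in range(n):
            t = np.linspace(0, 4, 4)
            y = post_slope * np.maximum(ct[i] + t - hstar, 0) + rng.normal(0, noise, 4)
            for tj, yj in zip(t, y):
                rows.append((f"h{i:03d}", 70 + tj, tj, yj, "cognition"))
        ids = [f"h{i:03d}" for i in range(n)]
        return make_long(rows), pd.Series(ct, index=ids)

    def test_recovers_known_break(self):
        cohort, ctimes = self._piecewise_cohort(60, 0.0, -0.3, 0.05, seed=51)
        hs = hinge_scan(cohort, ctimes, step=0.2)
        assert hs.hinge is not None
        assert abs(hs.hinge - 0.0) <= 0.2
        assert np.allclose(np.diff(hs.table["hinge"]), 0.2)

    def test_constant_slope_gives_sentinel(self):
        rng = np.random.default_rng(52)
        ct = rng.uniform(-2.5, 2.5, 60)
        rows = []
        for i in range(60):
            t = np.linspace(0, 4, 4)
            y = -0.1 * t + rng.normal(0, 0.05, 4)
            for tj, yj in zip(t, y):
                rows.append((f"h{i:03d}", 70 + tj, tj, yj, "cognition"))
        hs = hinge_scan(make_long(rows), pd.Series(ct, index=[f"h{i:03d}" for i in range(60)]),
                        step=0.2)
        assert hs.hinge is None

    def test_anchor_examples(self):
        np.testing.assert_allclose(anchor_ctime(np.array([-3.0, 0.0, 2.0]), 2.0),
                                   [-5.0, -2.0, 0.0])
        x = np.array([1.0, -4.0, 0.5])
        np.testing.assert_allclose(anchor_ctime(x, 0.0), x)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.integers(-2000, 2000).map(lambda i: i / 100.0),
            min_size=2, max_size=10, unique=True,
        ),
        st.integers(-1000, 1000).map(lambda i: i / 100.0),
    )
    def test_anchoring_preserves_order(self, ctimes, hinge):
        before = np.argsort(ctimes)
        after = np.argsort(anchor_ctime(np.array(ctimes), hinge))
        np.testing.assert_array_equal(before, after)


class TestCTimeAligner:
    def test_sklearn_contract(self):
        est = CTimeAligner(max_iter=17, tol=1e-3)
        params = est.get_params()
        assert params["max_iter"] == 17
        est.set_params(max_iter=23)
        assert est.get_params()["max_iter"] == 23

    def test_fit_sets_attributes_and_anchors(self, small_cognitive_cohort):
        cohort, truth = small_cognitive_cohort
        est = CTimeAligner(max_iter=120, hinge_step=0.5).fit(cohort)
        assert est.curve_params_.has_curvature
        assert len(est.ctimes_) == truth.subjects.shape[0]
        if est.hinge_ is not None:
            np.testing.assert_allclose(
                est.ctimes_["ctime"], est.ctimes_["delta"] - est.hinge_
            )
        # predict on the training table reproduces the fitted ordering
        pred = est.predict(cohort)
        merged = pred.merge(est.ctimes_, on="subject_id")
        rho, _ = spearman(merged["ctime_x"], merged["ctime_y"])
        assert rho > 0.999
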