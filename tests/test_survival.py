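"""Weibull evaluation, fitting, pooling and hazard-ratio adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcc_cea import (
    KMPoint,
    SurvivalCurve,
    TrialArm,
    WeibullParams,
    apply_hr,
    build_reference_curve,
    eval_weibull,
    fit_weibull,
    weibull_curve,
)


class TestEvalWeibull:
    @pytest.mark.parametrize(
        "scale,shape,t,expected,tol",
        [
            # interferon OS law at its published 21.8-month (15.9-cycle) median
            (0.0476218, 0.9666, 15.9, 0.5014, 1e-3),
            (0.693147, 1.0, 1.0, 0.5, 1e-6),  # exponential with unit half-life
            (0.25, 2.0, 0.0, 1.0, 0.0),  # S(0) = 1 for any law
        ],
    )
    def test_closed_form_values(self, scale, shape, t, expected, tol):
        got = eval_weibull(WeibullParams(scale=scale, shape=shape), t)
        assert got == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            eval_weibull(WeibullParams(0.1, 1.0), -0.5)

    def test_analytic_median_matches_curve(self):
        p = WeibullParams(0.2447073, 0.7914)
        assert eval_weibull(p, p.median()) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "bad", [dict(scale=-1, shape=1), dict(scale=1, shape=0), dict(scale=0.1, shape=1, correlation=-2)]
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            WeibullParams(**bad)


class TestFitWeibull:
    def test_noiseless_points_recover_generating_law_exactly(self):
        gen = WeibullParams(0.2447073, 0.7914)
        pts = [KMPoint(t, float(eval_weibull(gen, t))) for t in range(1, 21)]
        fit = fit_weibull(pts)
        assert fit.params.scale == pytest.approx(gen.scale, rel=1e-6)
        assert fit.params.shape == pytest.approx(gen.shape, rel=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_fit_is_inverse_of_eval(self):
        gen = WeibullParams(0.06, 1.1)
        pts = [KMPoint(t, float(eval_weibull(gen, t))) for t in (1, 3, 7, 12, 30)]
        fit = fit_weibull(pts)
        grid = np.linspace(0, 40, 81)
        np.testing.assert_allclose(
            eval_weibull(fit.params, grid), eval_weibull(gen, grid), atol=1e-9
        )

    def test_boundary_survival_points_excluded(self):
        gen = WeibullParams(0.3, 0.8)
        pts = [KMPoint(0.0, 1.0), KMPoint(50.0, 0.0)] + [
            KMPoint(t, float(eval_weibull(gen, t))) for t in (1, 2, 4)
        ]
        fit = fit_weibull(pts)
        assert fit.n_points == 3
        assert fit.params.scale == pytest.approx(gen.scale, rel=1e-6)

    def test_two_usable_points_rejected(self):
        pts = [KMPoint(1.0, 0.9), KMPoint(2.0, 0.8), KMPoint(3.0, 1.0)]
        with pytest.raises(ValueError, match="at least 3"):
            fit_weibull(pts)

    def test_scale_shape_estimates_anticorrelated(self):
        gen = WeibullParams(0.2, 0.9)
        rng = np.random.default_rng(7)
        pts = [
            KMPoint(t, float(np.clip(eval_weibull(gen, t) + rng.normal(0, 0.005), 1e-6, 1 - 1e-6)))
            for t in range(1, 25)
        ]
        fit = fit_weibull(pts)
        assert fit.params.correlation < -0.5


def _arm(label, n, scale_p=0.2, shape_p=0.8, scale_o=0.05, shape_o=1.0):
    return TrialArm(
        label=label,
        n_patients=n,
        pfs_params=WeibullParams(scale_p, shape_p),
        os_params=WeibullParams(scale_o, shape_o),
    )


class TestReferenceCurve:
    def test_identical_arms_give_the_common_curve(self):
        arms = [_arm(f"a{i}", 100 + i) for i in range(4)]
        ref = build_reference_curve(arms, "OS", 40)
        np.testing.assert_allclose(
            ref.values, eval_weibull(WeibullParams(0.05, 1.0), np.arange(41))
        )

    def test_equal_weight_mean_of_two_arms(self):
        a = _arm("a", 100, scale_o=0.1)
        b = _arm("b", 100, scale_o=0.3)
        ref = build_reference_curve([a, b], "OS", 10)
        at5 = 0.5 * (math.exp(-0.1 * 5) + math.exp(-0.3 * 5))
        assert ref.values[5] == pytest.approx(at5, abs=1e-12)

    def test_weighted_sum_matches_hand_computation(self, config):
        # spreadsheet-style oracle: weighted sum of the four OS laws at the
        # interferon arm's median OS time, recomputed independently
        t = 15  # nearest grid cycle to the 15.9-cycle median
        total = sum(a.n_patients for a in config.trials)
        expected = sum(
            a.n_patients / total * math.exp(-a.os_params.scale * t ** a.os_params.shape)
            for a in config.trials
        )
        ref = build_reference_curve(config.trials, "OS", 87)
        assert ref.values[t] == pytest.approx(expected, abs=1e-12)

    def test_order_and_uniform_scaling_invariance(self):
        arms = [_arm("a", 50, scale_p=0.1), _arm("b", 150, scale_p=0.3), _arm("c", 70, scale_p=0.22)]
        ref = build_reference_curve(arms, "PFS", 30)
        shuffled = build_reference_curve(arms[::-1], "PFS", 30)
        scaled = build_reference_curve(
            [TrialArm(a.label, a.n_patients * 7, a.pfs_params, a.os_params) for a in arms],
            "PFS",
            30,
        )
        np.testing.assert_allclose(ref.values, shuffled.values)
        np.testing.assert_allclose(ref.values, scaled.values)

    def test_empty_arm_list_rejected(self):
        with pytest.raises(ValueError):
            build_reference_curve([], "PFS", 10)


class TestApplyHr:
    def test_point_values(self):
        curve = weibull_curve(WeibullParams(math.log(2.0), 1.0), 5)  # S(1) = 0.5
        assert apply_hr(curve, 1.0).values[1] == pytest.approx(0.5)
        # sunitinib's PFS hazard ratio applied to a 50% survival fraction
        assert apply_hr(curve, 0.42).values[1] == pytest.approx(0.5 ** 0.42, abs=1e-12)
        assert apply_hr(curve, 3.0).values[0] == 1.0

    def test_nonpositive_hr_rejected(self):
        curve = weibull_curve(WeibullParams(0.1, 1.0), 5)
        with pytest.raises(ValueError):
            apply_hr(curve, 0.0)

    @given(
        hr_a=st.floats(0.1, 3.0),
        hr_b=st.floats(0.1, 3.0),
        scale=st.floats(0.01, 0.5),
        shape=st.floats(0.5, 1.5),
    )
    @settings(max_examples=60, deadline=None)
    def test_group_laws_and_curve_invariants(self, hr_a, hr_b, scale, shape):
        curve = weibull_curve(WeibullParams(scale, shape), 30)
        ident = apply_hr(curve, 1.0)
        np.testing.assert_array_equal(ident.values, curve.values)
        combined = apply_hr(apply_hr(curve, hr_a), hr_b)
        direct = apply_hr(curve, hr_a * hr_b)
        np.testing.assert_allclose(combined.values, direct.values, atol=1e-12)
        v = combined.values
        assert v[0] == 1.0 and np.all(v >= 0) and np.all(v <= 1)
        assert np.all(np.diff(v) <= 1e-12)

    def test_hr_below_one_raises_interior_points(self):
        curve = weibull_curve(WeibullParams(0.2, 0.9), 20)
        up = apply_hr(curve, 0.5).values
        down = apply_hr(curve, 2.0).values
        assert np.all(up[1:] >= curve.values[1:])
        assert np.all(down[1:] <= curve.values[1:])


class TestSurvivalCurveInvariants:
    def test_rejects_increasing_or_out_of_range(self):
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([1.0, 0.5, 0.6]))
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([0.9, 0.5]))
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([1.0, 1.2]))
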