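"""MR estimator battery: closed forms, nesting identities, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micromr.mr_core import (
    EggerRegression,
    IVWEstimator,
    MedianRatioEstimator,
    METHOD_ORDER,
    confidence_interval,
    heterogeneity,
    ivw,
    median_estimator,
    mr_egger,
    run_all_methods,
    wald_ratio,
)


def frame(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(bx.size)],
            "beta_x": bx,
            "se_x": np.full(bx.size, 0.02) if sx is None else np.asarray(sx, float),
            "beta_y": np.asarray(by, dtype=float),
            "se_y": np.asarray(sy, dtype=float),
        }
    )


class TestWaldRatio:
    def test_arithmetic(self):
        assert wald_ratio(0.5, -2.0, 0.4) == (pytest.approx(-4.0), pytest.approx(0.8))
        theta, se = wald_ratio(0.5, 0.0, 0.4)
        assert theta == 0.0 and se == pytest.approx(0.8)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 1.0, 0.1)

    def test_second_order_se_matches_monte_carlo(self):
        bx, sx, by, sy = 0.5, 0.05, -2.0, 0.4
        _, se2 = wald_ratio(bx, by, sy, se_x=sx, second_order=True)
        rng = np.random.default_rng(99)
        draws = rng.normal(by, sy, 1_000_000) / rng.normal(bx, sx, 1_000_000)
        assert se2 == pytest.approx(draws.std(), rel=0.05)


class TestIVW:
    def test_closed_form_oracle_random_fixtures(self):
        rng = np.random.default_rng(10)
        for J in (3, 5, 9, 20):
            bx = rng.uniform(0.05, 0.5, J)
            by = rng.normal(0, 2, J)
            sy = rng.uniform(0.5, 3, J)
            insts = frame(bx, by, sy)
            oracle = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
            res = ivw(insts, fixed_effect=True)
            assert res.estimate == pytest.approx(oracle, abs=1e-10)

    def test_single_instrument_equals_wald(self):
        insts = frame([0.4], [-2.0], [0.5])
        res = ivw(insts)
        theta, se = wald_ratio(0.4, -2.0, 0.5)
        assert (res.estimate, res.se) == (pytest.approx(theta), pytest.approx(se))

    def test_homogeneous_ratios_penalization_noop(self, three_insts=None):
        bx = np.array([0.2, 0.3, 0.5])
        insts = frame(bx, 3.0 * bx, [0.1, 0.1, 0.2])
        plain = ivw(insts)
        pen = ivw(insts, penalized=True)
        assert plain.estimate == pytest.approx(3.0, abs=1e-12)
        assert pen.estimate == pytest.approx(plain.estimate, abs=1e-12)
        het = heterogeneity(insts, plain)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.pvalue == pytest.approx(1.0)

    def test_random_effects_floor_never_shrinks_se(self, three_insts):
        fe = ivw(three_insts, fixed_effect=True)
        re = ivw(three_insts)
        assert re.se >= fe.se - 1e-15

    def test_penalization_downweights_outlier(self):
        bx = np.full(6, 0.3)
        by = 2.0 * bx
        by[5] = 5.0  # wild ratio
        insts = frame(bx, by, np.full(6, 0.3))
        plain = ivw(insts)
        pen = ivw(insts, penalized=True)
        assert abs(pen.estimate - 2.0) < abs(plain.estimate - 2.0)

    def test_robust_resists_outlier(self):
        bx = np.full(9, 0.3)
        by = 2.0 * bx + np.array([0, 0, 0, 0, 0, 0, 0, 0, 4.0])
        insts = frame(bx, by, np.full(9, 0.2))
        rob = ivw(insts, robust=True)
        plain = ivw(insts)
        assert abs(rob.estimate - 2.0) < abs(plain.estimate - 2.0)


class TestEgger:
    def test_constrained_intercept_reproduces_ivw(self, three_insts):
        e = EggerRegression(fit_intercept=False).fit(three_insts)
        assert e.estimate_ == pytest.approx(ivw(three_insts).estimate, abs=1e-12)

    def test_zero_intercept_data_recovery(self):
        # summary-level generator with wide instrument-strength spread so the
        # Egger slope is identified (high I^2_GX)
        rng = np.random.default_rng(6)
        theta = -25.0
        J, reps = 9, 200
        slopes, inters, inter_ok = [], [], []
        for _ in range(reps):
            alpha = rng.uniform(0.05, 0.3, J)
            sx = np.full(J, 0.01)
            sy = np.full(J, 1.5)
            bx = rng.normal(alpha, sx)
            by = rng.normal(theta * alpha, sy)
            fit = EggerRegression().fit(frame(bx, by, sy, sx))
            slopes.append(fit.estimate_)
            inters.append(fit.intercept_)
            inter_ok.append(abs(fit.intercept_) < 2 * fit.intercept_se_)
        slopes, inters = np.array(slopes), np.array(inters)
        assert np.mean(inters) == pytest.approx(0.0, abs=2 * inters.std() / np.sqrt(reps))
        assert np.mean(inter_ok) > 0.9
        assert np.mean(slopes) == pytest.approx(theta, abs=3 * slopes.std() / np.sqrt(reps))

    def test_directional_pleiotropy_lands_in_intercept(self):
        rng = np.random.default_rng(13)
        alpha = rng.uniform(0.05, 0.3, 50)
        pleio = 1.0  # constant direct effect on the outcome
        sy = np.full(50, 0.3)
        by = -10.0 * alpha + pleio + rng.normal(0, 0.3, 50)
        fit = EggerRegression().fit(frame(alpha, by, sy))
        assert fit.intercept_ == pytest.approx(1.0, abs=3 * fit.intercept_se_)
        assert fit.estimate_ == pytest.approx(-10.0, abs=3 * fit.se_)

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            EggerRegression().fit(frame([0.2, 0.3], [1.0, 2.0], [0.1, 0.1]))


class TestMedian:
    def test_simple_median_odd_count(self):
        insts = frame([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], [1.0, 1.0, 1.0])
        res = median_estimator(insts, "simple", n_boot=200, seed=0)
        assert res.estimate == pytest.approx(2.0)

    def test_dominant_weight_limit(self):
        # one instrument carries ~all weight -> weighted median ~ its ratio
        insts = frame([0.5, 0.2, 0.3], [2.5, 1.0, 0.3], [0.001, 5.0, 5.0])
        res = median_estimator(insts, "weighted", n_boot=200, seed=0)
        assert res.estimate == pytest.approx(5.0, abs=0.05)

    def test_equal_weights_weighted_equals_simple(self):
        insts = frame([0.3, 0.3, 0.3, 0.3], [1.2, 0.3, 2.1, 0.9], np.full(4, 0.7))
        simple = MedianRatioEstimator("simple", 200, 1).fit(insts)
        weighted = MedianRatioEstimator("weighted", 200, 1).fit(insts)
        assert weighted.estimate_ == pytest.approx(simple.estimate_, abs=1e-12)

    def test_bootstrap_se_stable_across_seeds(self, harmonized_nine):
        insts, _ = harmonized_nine
        a = MedianRatioEstimator("weighted", 5000, 11).fit(insts)
        b = MedianRatioEstimator("weighted", 5000, 77).fit(insts)
        assert a.se_ == pytest.approx(b.se_, rel=0.03)

    def test_small_bootstrap_rejected_by_default(self, three_insts):
        with pytest.raises(ValueError, match="n_boot"):
            MedianRatioEstimator("weighted", n_boot=50).fit(three_insts)
        # explicit opt-in works
        MedianRatioEstimator("weighted", n_boot=50, min_boot=10).fit(three_insts)

    def test_median_resists_minority_invalid_instruments(self):
        # 40% of instruments carry directional pleiotropy: the weighted
        # median stays near truth while IVW drifts
        rng = np.random.default_rng(30)
        theta = 2.0
        bias_med, bias_ivw = [], []
        for _ in range(50):
            alpha = rng.uniform(0.1, 0.4, 10)
            sy = np.full(10, 0.05)
            pleio = np.zeros(10)
            pleio[:4] = 0.4
            by = theta * alpha + pleio + rng.normal(0, 0.05, 10)
            insts = frame(alpha, by, sy)
            bias_med.append(median_estimator(insts, "weighted", 300, 5).estimate - theta)
            bias_ivw.append(ivw(insts).estimate - theta)
        assert abs(np.mean(bias_med)) < abs(np.mean(bias_ivw))


class TestHeterogeneity:
    def test_planted_outlier_dominates_contributions(self):
        bx = np.full(9, 0.3)
        by = 2.0 * bx
        by[4] += 3.0
        insts = frame(bx, by, np.full(9, 0.3))
        het = heterogeneity(insts, ivw(insts))
        assert int(np.argmax(het.contributions)) == 4
        assert het.Q == pytest.approx(sum(het.contributions))
        assert het.df == 8

    def test_null_q_mean_matches_chi2_df(self):
        # correctly specified null: beta_x exact, outcome noise matches se_y
        rng = np.random.default_rng(18)
        J, reps = 9, 1000
        qs = []
        for _ in range(reps):
            alpha = rng.uniform(0.1, 0.4, J)
            sy = np.full(J, 0.5)
            by = -3.0 * alpha + rng.normal(0, 0.5, J)
            insts = frame(alpha, by, sy, sx=np.full(J, 1e-8))
            qs.append(heterogeneity(insts, ivw(insts)).Q)
        assert np.mean(qs) == pytest.approx(J - 1, abs=4 * np.std(qs) / np.sqrt(reps))

    def test_egger_q_uses_j_minus_2(self, three_insts):
        het = heterogeneity(three_insts, mr_egger(three_insts))
        assert het.df == 1
        assert het.method == "egger_q"


class TestBattery:
    def test_row_order_and_ci_arithmetic(self, harmonized_nine):
        insts, _ = harmonized_nine
        table = run_all_methods(insts, seed=1, n_boot=300)
        assert list(table["method"]) == METHOD_ORDER
        assert (table["status"] == "ok").all()
        np.testing.assert_allclose(
            table["ci_low"], table["estimate"] - 1.959964 * table["se"], atol=1e-3
        )
        np.testing.assert_allclose(
            table["ci_high"], table["estimate"] + 1.959964 * table["se"], atol=1e-3
        )
        egger_rows = table["method"].str.contains("egger")
        assert table.loc[egger_rows, "intercept"].notna().all()
        assert table.loc[~egger_rows, "intercept"].isna().all()

    def test_scale_equivariance(self, harmonized_nine):
        insts, _ = harmonized_nine
        c = 3.7
        scaled = insts.copy()
        scaled["beta_x"] = scaled["beta_x"] * c
        scaled["se_x"] = scaled["se_x"] * c
        a = run_all_methods(insts, seed=2, n_boot=150)
        b = run_all_methods(scaled, seed=2, n_boot=150)
        np.testing.assert_allclose(b["estimate"], a["estimate"] / c, rtol=1e-6)

    def test_sign_equivariance(self, harmonized_nine):
        insts, _ = harmonized_nine
        flipped = insts.copy()
        flipped["beta_y"] = -flipped["beta_y"]
        a = run_all_methods(insts, seed=2, n_boot=150)
        b = run_all_methods(flipped, seed=2, n_boot=150)
        np.testing.assert_allclose(b["estimate"], -a["estimate"], rtol=1e-6)
        for m in ("ivw", "mr_egger", "penalized_ivw"):
            sa = a.loc[a["method"] == m, "se"].iloc[0]
            sb = b.loc[b["method"] == m, "se"].iloc[0]
            assert sb == pytest.approx(sa, rel=1e-9)


class TestCI:
    def test_symmetric_normal_interval(self):
        lo, hi = confidence_interval(-17.198, 14.415)
        assert lo == pytest.approx(-45.451, abs=1e-3)
        assert hi == pytest.approx(11.055, abs=1e-3)

    @given(st.floats(-50, 50), st.floats(0.01, 30))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_width_and_center(self, est, se):
        lo, hi = confidence_interval(est, se)
        assert (lo + hi) / 2 == pytest.approx(est, abs=1e-9)
        assert hi - lo == pytest.approx(2 * 1.959963985 * se, rel=1e-6)
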