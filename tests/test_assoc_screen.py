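"""Additive association models, interaction scans and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micromr import CohortConfig, simulate_cohort
from micromr.assoc_screen import (
    MonomorphicSNPError,
    bulk_linear_scan,
    fit_linear_additive,
    fit_logistic_additive,
    interaction_scan,
    rank_and_tabulate,
)
from micromr.genetics_io import CohortTable, GenotypeMatrix


def make_cohort(dosages: dict, phenotypes: dict) -> CohortTable:
    dos = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in dosages.items()})
    info = pd.DataFrame(
        {"chrom": "1", "allele_minor": "A", "allele_major": "G"}, index=dos.columns
    )
    return CohortTable(
        phenotypes=pd.DataFrame(phenotypes, index=dos.index),
        genotypes=GenotypeMatrix(dosages=dos, snp_info=info),
    )


class TestLinear:
    def test_noiseless_exact_fit(self):
        dosage = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        cohort = make_cohort({"snp": dosage}, {"glucose": 3.0 * dosage + 5.0})
        res = fit_linear_additive(cohort, "snp", ())
        assert res.beta == pytest.approx(3.0, abs=1e-10)
        assert res.pvalue < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(14)
        n = 30
        dosage = rng.binomial(2, 0.4, n)
        age = rng.normal(60, 5, n)
        sex = rng.integers(0, 2, n)
        y = 2.0 * dosage + 0.5 * age - 3.0 * sex + rng.normal(0, 4, n)
        cohort = make_cohort({"snp": dosage}, {"glucose": y, "age": age, "sex": sex})
        res = fit_linear_additive(cohort, "snp", ("age", "sex"))
        # brute-force normal equations
        X = np.column_stack([np.ones(n), dosage, age, sex])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        sigma2 = resid @ resid / (n - 4)
        se_hat = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        p_hat = 2 * stats.t.sf(abs(beta_hat[1] / se_hat), n - 4)
        assert res.beta == pytest.approx(beta_hat[1], abs=1e-8)
        assert res.se == pytest.approx(se_hat, abs=1e-8)
        assert res.pvalue == pytest.approx(p_hat, rel=1e-8)

    def test_planted_effect_recovery_at_cohort_scale(self):
        # planted beta close to the strongest screen hit: -7.9 at MAF 0.144
        cohort, _ = simulate_cohort(CohortConfig(), [(0.144, -7.9)], seed=41)
        snp = cohort.genotypes.snp_ids[0]
        res = fit_linear_additive(cohort, snp, "model5")
        assert res.beta == pytest.approx(-7.9, abs=2 * res.se)
        # crude-model SE matches the analytic OLS slope SE at this MAF and n
        crude = fit_linear_additive(cohort, snp, ())
        var_g = 2 * 0.144 * (1 - 0.144)
        se_analytic = cohort.phenotypes["glucose"].std() / np.sqrt(1020 * var_g)
        assert crude.se == pytest.approx(se_analytic, rel=0.15)

    def test_monomorphic_snp_raises(self):
        cohort = make_cohort({"snp": np.zeros(20)}, {"glucose": np.random.default_rng(0).normal(size=20)})
        with pytest.raises(MonomorphicSNPError):
            fit_linear_additive(cohort, "snp", ())

    def test_dosage_recoding_flips_beta_sign_only(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.3, 200)
        y = 1.5 * dosage + rng.normal(0, 3, 200)
        a = fit_linear_additive(make_cohort({"s": dosage}, {"glucose": y}), "s", ())
        b = fit_linear_additive(make_cohort({"s": 2 - dosage}, {"glucose": y}), "s", ())
        assert b.beta == pytest.approx(-a.beta, abs=1e-10)
        assert b.pvalue == pytest.approx(a.pvalue, rel=1e-10)
        assert b.se == pytest.approx(a.se, rel=1e-12)

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        dosage = np.tile([0.0, 1.0, 2.0], 20)
        ortho = np.tile([1.0, 1.0, 1.0, -1.0, -1.0, -1.0], 10)  # orthogonal to dosage
        assert abs(np.dot(ortho - ortho.mean(), dosage - dosage.mean())) < 1e-9
        y = 4.0 * dosage + 7.0
        base = fit_linear_additive(make_cohort({"s": dosage}, {"glucose": y, "z": ortho}), "s", ())
        adj = fit_linear_additive(make_cohort({"s": dosage}, {"glucose": y, "z": ortho}), "s", ("z",))
        assert adj.beta == pytest.approx(base.beta, abs=1e-10)


class TestLogistic:
    def test_two_by_two_odds_ratio(self):
        # dominant toy: dosage 1 vs 0; cross-product (20*20)/(10*10) = 4
        dosage = np.array([1] * 30 + [0] * 30)
        outcome = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        cohort = make_cohort({"s": dosage}, {"t2d": outcome})
        res = fit_logistic_additive(cohort, "s", ())
        assert res.odds_ratio == pytest.approx(4.0, rel=1e-6)

    def test_matches_newton_solver_oracle(self):
        rng = np.random.default_rng(5)
        n = 50
        dosage = rng.binomial(2, 0.4, n).astype(float)
        age = rng.normal(0, 1, n)
        logit = -0.3 + 0.8 * dosage + 0.5 * age
        yb = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        cohort = make_cohort({"s": dosage}, {"t2d": yb, "age": age})
        res = fit_logistic_additive(cohort, "s", ("age",))
        # independent Newton-Raphson IRLS
        X = np.column_stack([np.ones(n), dosage, age])
        b = np.zeros(3)
        for _ in range(50):
            mu = 1 / (1 + np.exp(-X @ b))
            W = mu * (1 - mu)
            step = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (yb - mu))
            b = b + step
            if np.max(np.abs(step)) < 1e-12:
                break
        assert res.beta == pytest.approx(b[1], abs=1e-6)

    def test_null_dosage_gives_or_near_one(self):
        rng = np.random.default_rng(8)
        dosage = rng.binomial(2, 0.3, 2000).astype(float)
        yb = rng.integers(0, 2, 2000).astype(float)
        res = fit_logistic_additive(make_cohort({"s": dosage}, {"t2d": yb}), "s", ())
        assert res.odds_ratio == pytest.approx(1.0, abs=3 * res.se)

    def test_separation_flagged_not_crashed(self):
        dosage = np.array([0.0] * 10 + [2.0] * 10)
        yb = np.array([0.0] * 10 + [1.0] * 10)  # perfect separation
        res = fit_logistic_additive(make_cohort({"s": dosage}, {"t2d": yb}), "s", ())
        assert res.converged is False


class TestInteractionScan:
    def _planted_cohort(self, beta1: float, beta2: float, seed: int = 0, n: int = 1200):
        rng = np.random.default_rng(seed)
        dosage = rng.binomial(2, 0.3, n).astype(float)
        modifier = rng.integers(0, 2, n).astype(float)
        y = np.where(modifier == 0, beta1 * dosage, beta2 * dosage) + rng.normal(0, 2, n)
        return make_cohort({"s": dosage}, {"glucose": y, "diet_high": modifier})

    def test_pure_interaction_recovered(self):
        cohort = self._planted_cohort(0.0, 12.0)
        out = interaction_scan(cohort, "diet_high", covariates=())
        row = out.iloc[0]
        assert row["p_interaction"] < 1e-4
        assert row["beta_strata1"] == pytest.approx(0.0, abs=2 * row["se_strata1"])
        assert row["beta_strata2"] == pytest.approx(12.0, abs=2 * row["se_strata2"])

    def test_equal_strata_effects_give_null_interaction(self):
        pvals = []
        for seed in range(30):
            cohort = self._planted_cohort(5.0, 5.0, seed=seed, n=500)
            out = interaction_scan(cohort, "diet_high", covariates=(), strata_fits=True)
            pvals.append(out["p_interaction"].iloc[0])
            b1, b2 = out["beta_strata1"].iloc[0], out["beta_strata2"].iloc[0]
            s = np.hypot(out["se_strata1"].iloc[0], out["se_strata2"].iloc[0])
            assert b1 - b2 == pytest.approx(0.0, abs=4 * s)
        assert (np.array(pvals) < 0.05).mean() <= 0.2  # roughly uniform p

    def test_monomorphic_stratum_reports_pooled_p(self):
        rng = np.random.default_rng(23)
        n = 400
        modifier = np.repeat([0.0, 1.0], n // 2)
        dosage = np.where(modifier == 0, 0.0, rng.binomial(2, 0.4, n))
        y = rng.normal(100, 5, n)
        cohort = make_cohort({"s": dosage}, {"glucose": y, "diet_high": modifier})
        out = interaction_scan(cohort, "diet_high", covariates=())
        assert np.isfinite(out["p_interaction"].iloc[0])
        assert out["beta_strata1"].isna().iloc[0]

    def test_nonbinary_modifier_rejected(self):
        cohort = self._planted_cohort(0.0, 0.0)
        cohort.phenotypes["diet_high"] = np.arange(len(cohort.phenotypes)) % 3
        with pytest.raises(ValueError, match="binary"):
            interaction_scan(cohort, "diet_high")


class TestRanking:
    def test_ascending_p_order(self):
        df = pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "beta": [1, 1, 1], "pvalue": [0.3, 0.01, 0.05]}
        )
        assert list(rank_and_tabulate(df)["snp_id"]) == ["b", "c", "a"]

    def test_tie_broken_by_abs_beta_then_id(self):
        df = pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "beta": [1.0, -2.0, -2.0], "pvalue": [0.05, 0.05, 0.05]}
        )
        assert list(rank_and_tabulate(df)["snp_id"]) == ["b", "c", "a"]

    def test_top_k_and_monotone_p(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(209)],
                "beta": rng.normal(size=209),
                "pvalue": rng.uniform(size=209),
            }
        )
        top = rank_and_tabulate(df, top_k=20)
        assert len(top) == 20
        assert top["pvalue"].is_monotonic_increasing

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_and_tabulate(pd.DataFrame(columns=["snp_id", "beta", "pvalue"]))


class TestBulkScan:
    def test_agrees_with_per_snp_fit(self):
        cohort, _ = simulate_cohort(
            CohortConfig(n_subjects=300), [(0.3, 2.0), (0.2, 0.0), (0.4, -1.0)], seed=55
        )
        fast = bulk_linear_scan(cohort, "model3")
        for i, snp in enumerate(cohort.genotypes.snp_ids):
            slow = fit_linear_additive(cohort, snp, "model3")
            assert fast["beta"].iloc[i] == pytest.approx(slow.beta, abs=1e-10)
            assert fast["se"].iloc[i] == pytest.approx(slow.se, abs=1e-10)
            assert fast["pvalue"].iloc[i] == pytest.approx(slow.pvalue, rel=1e-8)
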