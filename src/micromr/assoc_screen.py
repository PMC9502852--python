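"""Per-SNP additive association and interaction screens.

Linear models for fasting glucose and logistic models for type 2 diabetes,
each with a configurable covariate set; gene x diet and gene x sex
interaction scans with per-stratum effects; ranking utilities that mirror
the top-ranked output tables of a candidate-SNP screen.

Dosage is coded 0/1/2 copies of the minor allele; every fit is
complete-case on the SNP and covariates (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .genetics_io import CohortTable, minor_allele_frequency

__all__ = [
    "AssocResult",
    "InteractionResult",
    "MonomorphicSNPError",
    "MODEL_SETS",
    "fit_linear_additive",
    "fit_logistic_additive",
    "interaction_scan",
    "rank_and_tabulate",
    "outcome_summary_stats",
    "scan_linear",
]

#: Named covariate sets for the sequentially adjusted glucose models.  The
#: headline glucose model is model5; the diabetes screen uses sex+age+BMI.
MODEL_SETS = {
    "model1": (),
    "model2": ("sex",),
    "model3": ("sex", "age"),
    "model4": ("sex", "age", "t2d"),
    "model5": ("sex", "age", "t2d", "bmi", "medication"),
    "t2d_screen": ("sex", "age", "bmi"),
}

Z975 = float(stats.norm.ppf(0.975))


class MonomorphicSNPError(ValueError):
    """Raised when a SNP has no dosage variation in the analysis subset."""


@dataclass(frozen=True)
class AssocResult:
    """One SNP's additive-model association with one outcome."""

    snp_id: str
    beta: float  # mg/dL per minor allele, or log-odds for binary outcomes
    se: float
    pvalue: float
    maf: float
    n_used: int
    model_label: str
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    converged: bool = True

    def to_row(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "maf": self.maf,
            "n_used": self.n_used,
            "model_label": self.model_label,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class InteractionResult:
    """One SNP's gene x modifier interaction on a continuous outcome."""

    snp_id: str
    modifier_label: str
    p_interaction: float
    beta_interaction: float
    maf: float
    beta_strata1: float | None = None  # modifier == 0
    se_strata1: float | None = None
    beta_strata2: float | None = None  # modifier == 1
    se_strata2: float | None = None

    def to_row(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "beta_strata1": self.beta_strata1,
            "se_strata1": self.se_strata1,
            "beta_strata2": self.beta_strata2,
            "se_strata2": self.se_strata2,
            "p_interaction": self.p_interaction,
            "beta_interaction": self.beta_interaction,
            "modifier_label": self.modifier_label,
            "maf": self.maf,
        }


def _design(
    cohort: CohortTable, snp_id: str, covariates: Sequence[str]
) -> tuple[np.ndarray, pd.DataFrame, float]:
    """Complete-case design block: dosage + covariates, plus the MAF."""
    if snp_id not in cohort.genotypes.dosages.columns:
        raise KeyError(f"unknown SNP {snp_id}")
    missing_cov = [c for c in covariates if c not in cohort.phenotypes.columns]
    if missing_cov:
        raise KeyError(f"covariates absent from cohort: {missing_cov}")
    df = pd.DataFrame({"dosage": cohort.genotypes.dosages[snp_id]})
    for c in covariates:
        df[c] = cohort.phenotypes[c]
    mask = df.notna().all(axis=1)
    df = df.loc[mask]
    if df.empty or df["dosage"].nunique() < 2:
        raise MonomorphicSNPError(
            f"{snp_id}: no dosage variation in the complete-case subset"
        )
    maf = minor_allele_frequency(df["dosage"].to_numpy())
    return mask.to_numpy(), df, maf


def fit_linear_additive(
    cohort: CohortTable,
    snp_id: str,
    covariates: Sequence[str] | str = "model5",
    outcome: str = "glucose",
) -> AssocResult:
    """OLS of a continuous outcome on minor-allele dosage plus covariates.

    ``covariates`` may be a named model set (see :data:`MODEL_SETS`) or an
    explicit list of phenotype columns.  The reported p-value is two-sided
    from the t distribution with residual degrees of freedom.
    """
    label = covariates if isinstance(covariates, str) else "+".join(covariates) or "crude"
    cov = MODEL_SETS[covariates] if isinstance(covariates, str) else tuple(covariates)
    mask, df, maf = _design(cohort, snp_id, cov)
    y = cohort.phenotypes.loc[df.index, outcome].to_numpy(dtype=float)
    X = sm.add_constant(df.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y, X).fit()
    return AssocResult(
        snp_id=snp_id,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        pvalue=float(res.pvalues[1]),
        maf=maf,
        n_used=int(df.shape[0]),
        model_label=label,
    )


def fit_logistic_additive(
    cohort: CohortTable,
    snp_id: str,
    covariates: Sequence[str] | str = "t2d_screen",
    outcome: str = "t2d",
) -> AssocResult:
    """Maximum-likelihood logistic fit; OR and Wald CI for the minor allele.

    Separation or non-convergence yields a flagged (``converged=False``)
    result instead of an exception.
    """
    label = covariates if isinstance(covariates, str) else "+".join(covariates) or "crude"
    cov = MODEL_SETS[covariates] if isinstance(covariates, str) else tuple(covariates)
    mask, df, maf = _design(cohort, snp_id, cov)
    y = cohort.phenotypes.loc[df.index, outcome].to_numpy(dtype=float)
    X = sm.add_constant(df.to_numpy(dtype=float), has_constant="add")
    converged = True
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
        beta, se = float(res.params[1]), float(res.bse[1])
        pvalue = float(res.pvalues[1])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        converged, beta, se, pvalue = False, np.nan, np.nan, np.nan
    if not np.isfinite(se) or se > 1e3:  # quasi-separation blows up the SE
        converged = False
    return AssocResult(
        snp_id=snp_id,
        beta=beta,
        se=se,
        pvalue=pvalue,
        maf=maf,
        n_used=int(df.shape[0]),
        model_label=label,
        odds_ratio=float(np.exp(beta)) if np.isfinite(beta) else None,
        or_ci_low=float(np.exp(beta - Z975 * se)) if np.isfinite(se) else None,
        or_ci_high=float(np.exp(beta + Z975 * se)) if np.isfinite(se) else None,
        converged=converged,
    )


def _interaction_one(
    cohort: CohortTable,
    snp_id: str,
    modifier: str,
    covariates: Sequence[str],
    strata_fits: bool,
) -> InteractionResult:
    cov = [c for c in covariates if c != modifier]
    mask, df, maf = _design(cohort, snp_id, list(cov) + [modifier])
    y = cohort.phenotypes.loc[df.index, "glucose"].to_numpy(dtype=float)
    mod = df[modifier].to_numpy(dtype=float)
    dosage = df["dosage"].to_numpy(dtype=float)
    base = df[cov].to_numpy(dtype=float) if cov else np.empty((len(df), 0))
    X = np.column_stack([dosage, mod, dosage * mod, base])
    X = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, X).fit()
    p_int = float(res.pvalues[3])
    b_int = float(res.params[3])

    b1 = s1 = b2 = s2 = None
    if strata_fits:
        for level, (bname, sname) in ((0, ("b1", "s1")), (1, ("b2", "s2"))):
            sel = mod == level
            if sel.sum() >= 3 and len(np.unique(dosage[sel])) >= 2:
                Xs = sm.add_constant(
                    np.column_stack([dosage[sel], base[sel]]), has_constant="add"
                )
                rs = sm.OLS(y[sel], Xs).fit()
                val, sev = float(rs.params[1]), float(rs.bse[1])
            else:  # monomorphic stratum: strata effect undefined
                val, sev = None, None
            if level == 0:
                b1, s1 = val, sev
            else:
                b2, s2 = val, sev
    return InteractionResult(
        snp_id=snp_id,
        modifier_label=modifier,
        p_interaction=p_int,
        beta_interaction=b_int,
        maf=maf,
        beta_strata1=b1,
        se_strata1=s1,
        beta_strata2=b2,
        se_strata2=s2,
    )


def interaction_scan(
    cohort: CohortTable,
    modifier: str = "diet_high",
    covariates: Sequence[str] = ("sex", "age", "t2d", "bmi", "medication"),
    snp_ids: Iterable[str] | None = None,
    strata_fits: bool = True,
    qvalues: bool = False,
) -> pd.DataFrame:
    """Gene x modifier scan on fasting glucose, ranked by interaction p.

    The pooled model is ``glucose ~ dosage + modifier + dosage:modifier +
    covariates``; ``p_interaction`` is the Wald p of the product term.
    Per-stratum dosage effects come from refits inside each modifier level
    with the same covariates minus the modifier.  Benjamini-Hochberg
    q-values are an optional extension column.
    """
    if modifier not in cohort.phenotypes.columns:
        raise KeyError(f"modifier column {modifier!r} absent from cohort")
    levels = set(cohort.phenotypes[modifier].dropna().unique())
    if not levels <= {0, 1}:
        raise ValueError(f"modifier {modifier!r} must be binary 0/1")
    ids = list(snp_ids) if snp_ids is not None else cohort.genotypes.snp_ids
    rows = []
    for snp in ids:
        try:
            rows.append(
                _interaction_one(cohort, snp, modifier, covariates, strata_fits).to_row()
            )
        except MonomorphicSNPError:
            continue
    out = pd.DataFrame(rows).sort_values("p_interaction", kind="stable").reset_index(drop=True)
    if qvalues and not out.empty:
        out["q_bh"] = multipletests(out["p_interaction"], method="fdr_bh")[1]
    return out


def rank_and_tabulate(results: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Stable ascending-p ranking; ties broken by |beta| desc, then snp_id.

    Accepts any result table carrying ``pvalue`` (or ``p_interaction``) and
    ``beta`` columns.
    """
    if results.empty:
        raise ValueError("no results to rank")
    pcol = "pvalue" if "pvalue" in results.columns else "p_interaction"
    bcol = "beta" if "beta" in results.columns else "beta_interaction"
    df = results.copy()
    df["_absb"] = -df[bcol].abs()
    df = df.sort_values(
        [pcol, "_absb", "snp_id"], kind="stable"
    ).drop(columns="_absb").reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df


def scan_linear(
    cohort: CohortTable,
    covariates: Sequence[str] | str = "model5",
    snp_ids: Iterable[str] | None = None,
    qvalues: bool = False,
) -> pd.DataFrame:
    """Linear glucose screen across SNPs, ranked ascending by p."""
    ids = list(snp_ids) if snp_ids is not None else cohort.genotypes.snp_ids
    rows = []
    for snp in ids:
        try:
            rows.append(fit_linear_additive(cohort, snp, covariates).to_row())
        except MonomorphicSNPError:
            continue
    if not rows:
        raise ValueError("no polymorphic SNPs to scan")
    out = rank_and_tabulate(pd.DataFrame(rows))
    if qvalues:
        out["q_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def bulk_linear_scan(
    cohort: CohortTable,
    covariates: Sequence[str] | str = (),
    outcome: str = "glucose",
) -> pd.DataFrame:
    """Vectorized per-SNP OLS across many SNPs (inflation diagnostics).

    Residualizes the outcome and every dosage column on the covariates and
    computes the per-SNP slope, SE and t-based p in one pass; by
    Frisch-Waugh-Lovell these equal the dosage coefficient of the full
    joint fit.  Requires complete data (the synthetic generator emits none
    missing); use :func:`fit_linear_additive` for complete-case handling.
    """
    cov = MODEL_SETS[covariates] if isinstance(covariates, str) else tuple(covariates)
    y = cohort.phenotypes[outcome].to_numpy(dtype=float)
    G = cohort.genotypes.dosages.to_numpy(dtype=float)
    if np.isnan(G).any() or np.isnan(y).any():
        raise ValueError("bulk scan requires complete data")
    n = y.size
    X = np.column_stack([np.ones(n)] + [cohort.phenotypes[c].to_numpy(dtype=float) for c in cov])
    coef, *_ = np.linalg.lstsq(X, np.column_stack([y, G]), rcond=None)
    resid = np.column_stack([y, G]) - X @ coef
    y_res, G_res = resid[:, 0], resid[:, 1:]
    sxx = np.einsum("ij,ij->j", G_res, G_res)
    ok = sxx > 0
    slope = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    slope[ok] = (G_res[:, ok] * y_res[:, None]).sum(axis=0) / sxx[ok]
    df = n - X.shape[1] - 1
    rss = np.sum(y_res**2) - slope[ok] ** 2 * sxx[ok]
    se[ok] = np.sqrt(rss / df / sxx[ok])
    tvals = slope / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return pd.DataFrame(
        {
            "snp_id": cohort.genotypes.snp_ids,
            "beta": slope,
            "se": se,
            "tvalue": tvals,
            "chi2": tvals**2,
            "pvalue": pvals,
        }
    )


def outcome_summary_stats(
    cohort: CohortTable,
    snp_ids: Iterable[str] | None = None,
    covariates: Sequence[str] | str = (),
    outcome: str = "glucose",
    trait: str = "fasting_glucose",
) -> pd.DataFrame:
    """Per-SNP outcome associations as a summary-statistics table.

    This is the sample-2 half of a two-sample MR analysis: the effect
    allele is the cohort's minor allele and ``beta`` is mg/dL per allele.
    """
    ids = list(snp_ids) if snp_ids is not None else cohort.genotypes.snp_ids
    info = cohort.genotypes.snp_info
    rows = []
    for snp in ids:
        r = fit_linear_additive(cohort, snp, covariates, outcome=outcome)
        rows.append(
            {
                "snp_id": snp,
                "chrom": info.loc[snp, "chrom"],
                "effect_allele": info.loc[snp, "allele_minor"],
                "other_allele": info.loc[snp, "allele_major"],
                "eaf": r.maf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n_used,
                "trait": trait,
            }
        )
    return pd.DataFrame(rows)
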