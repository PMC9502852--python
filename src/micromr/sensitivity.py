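"""Leave-one-out influence analysis and outlier exclusion for MR fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import mr_core
from .mr_core import IVWEstimator, confidence_interval, heterogeneity, run_all_methods

__all__ = ["leave_one_out", "drop_and_refit", "forest_data"]


def leave_one_out(insts: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """IVW refits each omitting one instrument, plus the full-set row.

    Returns J+1 rows: one per excluded SNP and an ``All`` row identical to
    the full-set IVW.  The ``influential`` flag marks the SNP whose
    omission shifts the estimate most, provided its own ratio estimate
    opposes the pooled sign or its Cochran-Q contribution has p < 0.05 —
    a formalization of the visual judgment applied to leave-one-out and
    scatter displays.
    """
    if len(insts) < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    full = IVWEstimator().fit(insts)
    het = heterogeneity(insts, full)
    q_p = stats.chi2.sf(np.asarray(het.contributions), df=1)
    ratios = insts["beta_y"].to_numpy() / insts["beta_x"].to_numpy()

    rows = []
    deltas = np.empty(len(insts))
    for i in range(len(insts)):
        sub = insts.drop(insts.index[i])
        fit = IVWEstimator().fit(sub)
        lo, hi = fit.ci_
        deltas[i] = fit.estimate_ - full.estimate_
        rows.append(
            {
                "excluded_snp_id": insts.iloc[i]["snp_id"] if "snp_id" in insts.columns else str(i),
                "estimate": fit.estimate_,
                "se": fit.se_,
                "ci_low": lo,
                "ci_high": hi,
                "delta_vs_full": deltas[i],
                "influential": False,
            }
        )
    lo, hi = full.ci_
    rows.append(
        {
            "excluded_snp_id": "All",
            "estimate": full.estimate_,
            "se": full.se_,
            "ci_low": lo,
            "ci_high": hi,
            "delta_vs_full": 0.0,
            "influential": False,
        }
    )
    out = pd.DataFrame(rows)
    top = int(np.argmax(np.abs(deltas)))
    sign_opposes = ratios[top] * full.estimate_ < 0
    if sign_opposes or q_p[top] < 0.05:
        out.loc[top, "influential"] = True
    return out


def drop_and_refit(
    insts: pd.DataFrame, drop_ids: list[str], seed: int | None = None, n_boot: int = 5000
) -> dict:
    """Re-run the full method battery after excluding named instruments.

    Returns a dict with ``before``/``after`` method tables and
    ``heterogeneity_before``/``heterogeneity_after`` (Egger Q' when >= 3
    instruments remain, else IVW Q).
    """
    unknown = set(drop_ids) - set(insts["snp_id"])
    if unknown:
        raise KeyError(f"drop_ids not among instruments: {sorted(unknown)}")
    reduced = insts[~insts["snp_id"].isin(drop_ids)].reset_index(drop=True)
    if len(reduced) < 3:
        import warnings

        warnings.warn("fewer than 3 instruments remain; median/Egger rows will fail")
    before = run_all_methods(insts, seed=seed, n_boot=n_boot)
    after = run_all_methods(reduced, seed=seed, n_boot=n_boot)

    def _het(frame, table):
        ivw_row = table[table["method"] == "ivw"].iloc[0]
        est = mr_core.MREstimate(
            "ivw", ivw_row["estimate"], ivw_row["se"], ivw_row["ci_low"],
            ivw_row["ci_high"], ivw_row["pvalue"], int(ivw_row["n_instruments"]),
        )
        return heterogeneity(frame, est)

    return {
        "before": before,
        "after": after,
        "heterogeneity_before": _het(insts, before),
        "heterogeneity_after": _het(reduced, after) if len(reduced) >= 2 else None,
        "dropped": list(drop_ids),
    }


def forest_data(insts: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios with CIs plus the pooled IVW row (forest plot)."""
    rows = []
    for _, r in insts.iterrows():
        theta, se = mr_core.wald_ratio(r["beta_x"], r["beta_y"], r["se_y"])
        lo, hi = confidence_interval(theta, se)
        rows.append(
            {"snp_id": r.get("snp_id", ""), "estimate": theta, "se": se, "ci_low": lo, "ci_high": hi}
        )
    pooled = IVWEstimator().fit(insts)
    lo, hi = pooled.ci_
    rows.append(
        {"snp_id": "All (IVW)", "estimate": pooled.estimate_, "se": pooled.se_, "ci_low": lo, "ci_high": hi}
    )
    return pd.DataFrame(rows)
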