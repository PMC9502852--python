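"""Instrument selection and exposure/outcome harmonization for two-sample MR.

Candidate instruments are host SNPs associated with a microbial-trait
abundance in an exposure-sample mbGWAS.  Selection enforces the classic MR
relevance assumptions (association p-value, F statistic, outcome-sample
MAF) and removes known pleiotropic loci; harmonization rewrites both
samples onto a common effect allele, orienting the exposure effect to be
abundance-increasing, and drops irreconcilable or ambiguous palindromic
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SelectionPolicy",
    "HarmonizedInstrument",
    "NoValidInstrumentsError",
    "f_statistic",
    "select_instruments",
    "harmonize",
    "harmonize_all",
    "instruments_frame",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Known pleiotropic loci excluded by default: the MCM6/LCT lactase region,
#: whose association with Bifidobacterium runs through milk intake.
DEFAULT_EXCLUSIONS = frozenset({"rs182549", "rs4988235"})


class NoValidInstrumentsError(ValueError):
    """Raised when selection leaves no usable instrument."""


@dataclass(frozen=True)
class SelectionPolicy:
    """Thresholds governing instrument selection.

    ``p_primary`` is the preferred genome-wide threshold; ``p_fallback``
    applies when very few SNPs reach it.  ``maf_min_mr`` is enforced in the
    outcome sample; ``f_min`` is the weak-instrument bound on (beta/se)^2.
    """

    p_primary: float = 5e-8
    p_fallback: float = 1e-5
    maf_min_assoc: float = 0.05
    maf_min_mr: float = 0.10
    f_min: float = 10.0
    exclusion_list: frozenset[str] = DEFAULT_EXCLUSIONS
    min_primary_hits: int = 3  # fewer than this falls back to p_fallback
    palindrome_window: tuple[float, float] = (0.42, 0.58)

    def __post_init__(self) -> None:
        if self.p_primary > self.p_fallback:
            raise ValueError("p_primary must be <= p_fallback")
        for name in ("p_primary", "p_fallback", "maf_min_assoc", "maf_min_mr", "f_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's exposure/outcome effect pair on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    f_stat: float
    trait: str | None = None

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError(f"{self.snp_id}: SEs must be positive")
        if self.beta_x < 0:
            raise ValueError(f"{self.snp_id}: beta_x must be >= 0 after orientation")


def f_statistic(beta: float, se: float) -> float:
    """Per-instrument strength F = (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return float((beta / se) ** 2)


def select_instruments(
    exposure_stats: pd.DataFrame,
    policy: SelectionPolicy | None = None,
    outcome_mafs: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Filter exposure summary statistics down to valid MR instruments.

    Checks, in a fixed per-SNP order: association p-value (primary
    threshold, falling back to ``p_fallback`` when fewer than
    ``min_primary_hits`` reach it), instrument strength F, outcome-sample
    MAF, and the pleiotropic-exclusion list.  Returns the surviving rows
    (input order preserved, but the result is order-independent) plus an
    audit log with one ``{"snp_id", "action", "reason"}`` record per
    removal.
    """
    if policy is None:
        policy = SelectionPolicy()
    df = exposure_stats.copy()
    fvals = (df["beta"] / df["se"]) ** 2
    n_primary = int((df["pvalue"] <= policy.p_primary).sum())
    p_thresh = policy.p_primary if n_primary >= policy.min_primary_hits else policy.p_fallback

    audit: list[dict] = []
    keep = []
    for idx, row in df.iterrows():
        snp = row["snp_id"]
        reason = None
        if row["pvalue"] > p_thresh:
            reason = "pvalue"
        elif fvals.loc[idx] <= policy.f_min:
            reason = "weak_instrument"
        elif outcome_mafs is not None and outcome_mafs.get(snp, np.nan) < policy.maf_min_mr:
            reason = "low_outcome_maf"
        elif outcome_mafs is not None and snp not in outcome_mafs:
            reason = "missing_in_outcome"
        elif snp in policy.exclusion_list:
            reason = "pleiotropic_exclusion"
        if reason is None:
            keep.append(idx)
            audit.append({"snp_id": snp, "action": "retain", "reason": ""})
        else:
            audit.append({"snp_id": snp, "action": "remove", "reason": reason})
    selected = df.loc[keep].reset_index(drop=True)
    if selected.empty:
        raise NoValidInstrumentsError("no valid instruments survive selection")
    return selected, audit


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a.upper()) == b.upper()


def _alleles_match(ea1: str, oa1: str, ea2: str, oa2: str) -> str | None:
    """How sample-2 alleles map onto sample-1 alleles.

    Returns 'same', 'swap', 'flip_same', 'flip_swap' or None.
    """
    ea1, oa1, ea2, oa2 = (x.upper() for x in (ea1, oa1, ea2, oa2))
    if (ea2, oa2) == (ea1, oa1):
        return "same"
    if (ea2, oa2) == (oa1, ea1):
        return "swap"
    c = _COMPLEMENT
    if ea2 in c and oa2 in c:
        if (c[ea2], c[oa2]) == (ea1, oa1):
            return "flip_same"
        if (c[ea2], c[oa2]) == (oa1, ea1):
            return "flip_swap"
    return None


def harmonize(
    exposure: pd.Series | dict,
    outcome: pd.Series | dict,
    policy: SelectionPolicy | None = None,
) -> HarmonizedInstrument:
    """Align one SNP's exposure and outcome records on a common allele.

    The effect allele is oriented so the exposure beta is non-negative
    (abundance-increasing); the outcome beta is then expressed per copy of
    that same allele, negating when the outcome's effect allele is the
    other allele and strand-complementing when the allele pairs only match
    after A<->T / C<->G flipping.  Palindromic variants are kept only when
    both effect-allele frequencies are available, lie outside the
    configured ambiguity window and sit on the same side of 0.5.

    Raises ``ValueError`` with reason 'allele_mismatch' or
    'palindromic_ambiguous' for variants that cannot be aligned.
    """
    if policy is None:
        policy = SelectionPolicy()
    exp = dict(exposure)
    out = dict(outcome)
    if exp["snp_id"] != out["snp_id"]:
        raise ValueError("snp_id mismatch between exposure and outcome")
    snp = exp["snp_id"]

    rel = _alleles_match(
        exp["effect_allele"], exp["other_allele"], out["effect_allele"], out["other_allele"]
    )
    if rel is None:
        raise ValueError(f"{snp}: allele_mismatch")

    beta_y = float(out["beta"])
    eaf_y = out.get("eaf")
    if rel in ("swap", "flip_swap"):
        beta_y = -beta_y
        eaf_y = None if eaf_y is None or pd.isna(eaf_y) else 1.0 - float(eaf_y)

    if _is_palindromic(exp["effect_allele"], exp["other_allele"]):
        eaf_x = exp.get("eaf")
        lo, hi = policy.palindrome_window
        ok = (
            eaf_x is not None
            and eaf_y is not None
            and not pd.isna(eaf_x)
            and not pd.isna(eaf_y)
            and not (lo <= float(eaf_x) <= hi)
            and not (lo <= float(eaf_y) <= hi)
            and (float(eaf_x) - 0.5) * (float(eaf_y) - 0.5) > 0
        )
        if not ok:
            raise ValueError(f"{snp}: palindromic_ambiguous")

    beta_x = float(exp["beta"])
    ea, oa = exp["effect_allele"].upper(), exp["other_allele"].upper()
    if beta_x < 0:  # orient to the abundance-increasing allele
        beta_x, beta_y = -beta_x, -beta_y
        ea, oa = oa, ea

    return HarmonizedInstrument(
        snp_id=snp,
        effect_allele=ea,
        other_allele=oa,
        beta_x=beta_x,
        se_x=float(exp["se"]),
        beta_y=beta_y,
        se_y=float(out["se"]),
        f_stat=f_statistic(float(exp["beta"]), float(exp["se"])),
        trait=exp.get("trait"),
    )


def harmonize_all(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    policy: SelectionPolicy | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Harmonize every shared SNP; returns (instrument frame, audit log)."""
    out_by_snp = {r["snp_id"]: r for _, r in outcome_stats.iterrows()}
    rows, audit = [], []
    for _, exp in exposure_stats.iterrows():
        snp = exp["snp_id"]
        if snp not in out_by_snp:
            audit.append({"snp_id": snp, "action": "drop", "reason": "missing_in_outcome"})
            continue
        try:
            inst = harmonize(exp, out_by_snp[snp], policy)
        except ValueError as err:
            reason = str(err).split(": ", 1)[-1]
            audit.append({"snp_id": snp, "action": "drop", "reason": reason})
            continue
        rows.append(inst)
        audit.append({"snp_id": snp, "action": "harmonize", "reason": ""})
    return instruments_frame(rows), audit


def instruments_frame(instruments: list[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabular view of harmonized instruments consumed by the MR estimators."""
    return pd.DataFrame(
        [
            {
                "snp_id": i.snp_id,
                "effect_allele": i.effect_allele,
                "other_allele": i.other_allele,
                "beta_x": i.beta_x,
                "se_x": i.se_x,
                "beta_y": i.beta_y,
                "se_y": i.se_y,
                "f_stat": i.f_stat,
                "trait": i.trait,
            }
            for i in instruments
        ]
    )
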