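"""Genotype and summary-statistics I/O plus variant-level quality control.

Genotypes are held as additive dosages (0/1/2 copies of the minor allele
after QC orientation) with missing values kept as NaN — downstream
regressions are complete-case per SNP, never imputed.  Summary statistics
travel as tidy tab-separated tables with one row per SNP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUMMARY_COLUMNS",
    "SummaryStat",
    "GenotypeMatrix",
    "CohortTable",
    "QCReport",
    "read_summary_stats",
    "write_summary_stats",
    "read_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "minor_allele_frequency",
    "hwe_test",
    "apply_qc",
    "genomic_lambda",
    "qq_data",
]

#: Median of the 1-df chi-square distribution, the denominator of the
#: genomic inflation factor.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...

#: Mandatory columns of the summary-statistics dialect; ``eaf``, ``n``,
#: ``chrom`` and ``trait`` are optional and written as '.' when missing.
SUMMARY_COLUMNS = [
    "snp_id",
    "chrom",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "trait",
]

_MANDATORY = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


@dataclass(frozen=True)
class SummaryStat:
    """One SNP's association with one trait in one sample."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None
    chrom: str | None = None
    trait: str | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive dosage matrix with per-SNP metadata.

    ``dosages`` is a float DataFrame (NaN = missing); ``snp_info`` is indexed
    by snp_id with columns ``chrom``, ``allele_minor``, ``allele_major``.
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snp_info.index):
            raise ValueError("dosage columns and snp_info index differ")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class CohortTable:
    """Individual-level phenotypes plus the genotype matrix of one cohort.

    ``phenotypes`` is indexed like ``genotypes.dosages`` and carries at least
    ``glucose`` (mg/dL), ``t2d`` (0/1), ``sex`` (1 = male), ``age`` (years),
    ``bmi`` (kg/m^2), ``medication`` (0/1) and ``diet_score`` (0-14).
    """

    phenotypes: pd.DataFrame
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        if not self.phenotypes.index.equals(self.genotypes.dosages.index):
            raise ValueError("phenotype and genotype subject indices differ")

    @property
    def n_subjects(self) -> int:
        return self.phenotypes.shape[0]


@dataclass
class QCReport:
    """Per-SNP QC metrics and the bookkeeping of every removal."""

    per_snp: pd.DataFrame  # maf, hwe_p, call_rate, fail_reason ('' = pass)
    thresholds: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> dict:
        reasons = self.per_snp.loc[self.per_snp["fail_reason"] != "", "fail_reason"]
        return reasons.value_counts().to_dict()

    @property
    def retained(self) -> list[str]:
        return list(self.per_snp.index[self.per_snp["fail_reason"] == ""])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "n_input": int(self.per_snp.shape[0]),
            "n_retained": len(self.retained),
            "n_removed": self.n_removed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path: str | Path) -> None:
        self.per_snp.to_csv(path, sep="\t", na_rep=".")


# ---------------------------------------------------------------------------
# summary statistics I/O


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-style summary TSV (``.`` meaning missing)."""
    df = pd.read_csv(path, sep="\t", na_values=".", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"summary table lacks mandatory columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("summary table contains non-positive SEs")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# genotype I/O


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load GT calls from a VCF 4.x file as ALT-allele dosages.

    Orientation to the minor allele happens later in :func:`apply_qc`; here
    dosage simply counts ALT alleles.  Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is relatively slow

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    info: list[dict] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{var.ID}: multi-allelic records are not supported")
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 gt_types uses 3 for
        # hom-alt with 2 meaning unknown), use genotypes to stay explicit
        dos = np.empty(len(samples), dtype=float)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            dos[i] = np.nan if (a < 0 or b < 0) else float((a > 0) + (b > 0))
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        rows[snp_id] = dos
        info.append(
            {
                "snp_id": snp_id,
                "chrom": str(var.CHROM),
                "allele_minor": var.ALT[0],
                "allele_major": var.REF,
            }
        )
    dosages = pd.DataFrame(rows, index=samples)
    snp_info = pd.DataFrame(info).set_index("snp_id")
    return GenotypeMatrix(dosages=dosages, snp_info=snp_info)


def read_dosage_tsv(
    path: str | Path, snp_info: pd.DataFrame | None = None
) -> GenotypeMatrix:
    """Read the fixture dialect: subjects x SNPs, header row of rsIDs."""
    dosages = pd.read_csv(path, sep="\t", index_col=0, na_values=".")
    dosages.columns = dosages.columns.astype(str)
    if snp_info is None:
        snp_info = pd.DataFrame(
            {
                "chrom": "1",
                "allele_minor": "A",
                "allele_major": "G",
            },
            index=dosages.columns,
        )
    return GenotypeMatrix(dosages=dosages, snp_info=snp_info)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    genotypes.dosages.to_csv(path, sep="\t", na_rep=".")


# ---------------------------------------------------------------------------
# QC primitives


def minor_allele_frequency(dosages: Iterable[float]) -> float:
    """Minor allele frequency of one SNP's dosage vector.

    Returns ``min(f, 1 - f)`` with ``f`` the frequency of the counted
    allele; missing (NaN) entries are excluded.
    """
    arr = np.asarray(list(dosages) if not isinstance(dosages, np.ndarray) else dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    f = arr.sum() / (2.0 * arr.size)
    return float(min(f, 1.0 - f))


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """One-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts are ``n*p^2, 2n*p*q, n*q^2`` from the observed allele
    frequency.  No continuity correction.  Monomorphic input returns
    ``(0.0, 1.0)`` (a fixed allele is trivially in equilibrium).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_p_from_dosages(arr: np.ndarray) -> float:
    arr = arr[~np.isnan(arr)]
    n_aa = int((arr == 0).sum())
    n_het = int((arr == 1).sum())
    n_AA = int((arr == 2).sum())
    if n_aa + n_het + n_AA == 0:
        return np.nan
    return hwe_test(n_AA, n_het, n_aa)[1]


def apply_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
    call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Variant-level QC in a fixed order: autosome, MAF, HWE, call rate.

    A SNP is recorded under the first filter it fails, so removal counts are
    reproducible.  Surviving dosages are re-oriented to count the minor
    allele (frequency of the counted allele <= 0.5).
    """
    if genotypes.dosages.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    dos = genotypes.dosages
    info = genotypes.snp_info
    metrics = []
    for snp in dos.columns:
        arr = dos[snp].to_numpy(dtype=float)
        nonmiss = ~np.isnan(arr)
        call_rate = nonmiss.mean()
        maf = np.nan
        hwe_p = np.nan
        if nonmiss.any():
            maf = minor_allele_frequency(arr[nonmiss])
            hwe_p = _hwe_p_from_dosages(arr)
        reason = ""
        if str(info.loc[snp, "chrom"]) not in AUTOSOMES:
            reason = "non_autosomal"
        elif not nonmiss.any() or maf < maf_min:
            reason = "maf"
        elif hwe_p < hwe_p_min:
            reason = "hwe"
        elif call_rate < call_rate_min:
            reason = "call_rate"
        metrics.append(
            {"snp_id": snp, "maf": maf, "hwe_p": hwe_p, "call_rate": call_rate, "fail_reason": reason}
        )
    per_snp = pd.DataFrame(metrics).set_index("snp_id")
    report = QCReport(
        per_snp=per_snp,
        thresholds={
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "call_rate_min": call_rate_min,
        },
    )
    keep = report.retained
    new_dos = dos[keep].copy()
    new_info = info.loc[keep].copy()
    # orient to the minor allele so dosage counts minor-allele copies
    for snp in keep:
        arr = new_dos[snp].to_numpy(dtype=float)
        f = np.nanmean(arr) / 2.0
        if f > 0.5:
            new_dos[snp] = 2.0 - new_dos[snp]
            a, b = new_info.loc[snp, "allele_minor"], new_info.loc[snp, "allele_major"]
            new_info.loc[snp, "allele_minor"] = b
            new_info.loc[snp, "allele_major"] = a
    return GenotypeMatrix(dosages=new_dos, snp_info=new_info), report


# ---------------------------------------------------------------------------
# inflation diagnostics


def genomic_lambda(chi2_values: Iterable[float] | None = None, *, pvalues: Iterable[float] | None = None) -> float:
    """Genomic inflation factor: median association chi2 over the chi2_1 median.

    Accepts 1-df chi-square statistics directly, or p-values which are
    converted through the inverse chi2_1 survival function.
    """
    if (chi2_values is None) == (pvalues is None):
        raise ValueError("pass exactly one of chi2_values or pvalues")
    if pvalues is not None:
        p = np.asarray(list(pvalues), dtype=float)
        if p.size == 0:
            raise ValueError("empty p-value vector")
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        chi2 = stats.chi2.isf(p, df=1)
    else:
        chi2 = np.asarray(list(chi2_values), dtype=float)
        if chi2.size == 0:
            raise ValueError("empty chi-square vector")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_data(pvalues: Iterable[float]) -> pd.DataFrame:
    """Expected vs observed -log10(p) pairs for a Q-Q plot.

    Observed p-values are sorted ascending; the expected quantile of rank i
    (1-based) is ``i / (n + 1)``.
    """
    p = np.sort(np.asarray(list(pvalues), dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    ranks = np.arange(1, p.size + 1)
    expected = ranks / (p.size + 1.0)
    return pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10(expected),
            "observed_neglog10_p": -np.log10(p),
        }
    )


def summary_row(stat: SummaryStat) -> dict:
    """Flatten a SummaryStat into a summary-table row dict."""
    return {
        "snp_id": stat.snp_id,
        "chrom": stat.chrom,
        "effect_allele": stat.effect_allele,
        "other_allele": stat.other_allele,
        "eaf": stat.eaf,
        "beta": stat.beta,
        "se": stat.se,
        "pvalue": stat.pvalue,
        "n": stat.n,
        "trait": stat.trait,
    }
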