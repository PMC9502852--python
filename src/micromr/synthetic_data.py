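"""Synthetic cohorts and two-sample summary statistics with known truth.

The generator emulates the study design this package analyzes: an elderly
Mediterranean cohort of ~1020 subjects at high cardiovascular risk (fasting
glucose ~120 mg/dL, type 2 diabetes prevalence ~46.5%, 14-point diet
adherence score averaging ~8.5), and an independent exposure sample of 5959
subjects contributing per-SNP summary statistics for a latent microbial
trait.  Every simulated quantity is recorded in a :class:`GroundTruth` so
downstream stages have parameter-recovery tests.

Instruments are simulated independent (no linkage disequilibrium), which is
exactly the independence the MR model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .genetics_io import CohortTable, GenotypeMatrix

__all__ = [
    "CohortConfig",
    "InstrumentConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_two_sample",
]

# Glucose effects of the covariates, in mg/dL: the male-female glucose gap
# in the emulated population is ~10 mg/dL; age and BMI effects are mild.
SEX_EFFECT = 9.9
AGE_EFFECT = 0.2  # per year, centered
BMI_EFFECT = 0.4  # per kg/m^2, centered

#: log-odds of type 2 diabetes per mg/dL of fasting glucose used when
#: calibrating the prevalence intercept.
T2D_GLUCOSE_SLOPE = 0.04

# Non-palindromic allele pairs used for simulated SNPs.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass(frozen=True)
class CohortConfig:
    """Marginal targets of the simulated outcome cohort."""

    n_subjects: int = 1020
    prop_male: float = 0.364
    glucose_mean: float = 120.1  # mg/dL
    glucose_sd: float = 38.3  # mg/dL; back-derived from SE 1.2 at n=1020
    t2d_prevalence: float = 0.465
    diet_mean: float = 8.5  # points on the 0-14 adherence scale
    diet_high_cutoff: int = 9
    age_mean: float = 66.9
    age_sd: float = 6.4
    bmi_mean: float = 30.6
    bmi_sd: float = 5.1
    medication_rate_in_t2d: float = 0.80
    noise_sd: float | None = None  # overrides the glucose_sd calibration

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in ("prop_male", "t2d_prevalence", "medication_rate_in_t2d"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.glucose_sd <= 0:
            raise ValueError("glucose_sd must be > 0")
        if not (1 <= self.diet_high_cutoff <= 14):
            raise ValueError("diet_high_cutoff must lie in 1..14")
        if not (0.0 <= self.diet_mean <= 14.0):
            raise ValueError("diet_mean must lie on the 0-14 scale")


@dataclass(frozen=True)
class InstrumentConfig:
    """Design of the simulated instrument set and exposure sample.

    ``alpha_range`` holds per-allele effects on the latent microbial trait
    (SD units).  The defaults put the true exposure-association z-score near
    5.5-5.8 at ``n_sample1`` — i.e. p ~ 4e-8..8e-9 and F ~ 30, the
    instrument strength of a strong mbGWAS hit.
    """

    n_instruments: int = 9
    maf_range: tuple[float, float] = (0.15, 0.45)
    alpha_range: tuple[float, float] = (0.11, 0.15)
    n_sample1: int = 5959
    theta_true: float = 0.0  # mg/dL glucose per SD of exposure
    pleiotropy_effects: tuple[float, ...] | None = None  # direct SNP->glucose
    outlier_index: int | None = None
    # direct outlier effect, mg/dL per allele; sized so omitting the outlier
    # shifts the pooled IVW estimate by ~11 mg/dL, the influence scale of a
    # single opposite-direction pleiotropic instrument among nine
    outlier_effect: float = 12.0

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ValueError("n_instruments must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.pleiotropy_effects is not None and len(self.pleiotropy_effects) != self.n_instruments:
            raise ValueError("pleiotropy_effects length must equal n_instruments")
        if self.outlier_index is not None and not (0 <= self.outlier_index < self.n_instruments):
            raise ValueError("outlier_index out of range")


@dataclass(frozen=True)
class GroundTruth:
    """Verbatim record of the parameters behind one simulated dataset."""

    seed: int
    theta_true: float = 0.0
    snp_ids: tuple[str, ...] = ()
    maf: tuple[float, ...] = ()
    alpha: tuple[float, ...] = ()  # per-allele effect on the exposure
    beta_glucose: tuple[float, ...] = ()  # direct per-allele effect on glucose
    pleiotropy: tuple[float, ...] = ()

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _split_seed(seed: int, n: int) -> list[np.random.Generator]:
    """Named sub-streams off a single master seed."""
    seqs = np.random.SeedSequence(int(seed)).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def _simulate_genotypes(
    rng: np.random.Generator, n: int, mafs: Sequence[float], snp_ids: Sequence[str]
) -> GenotypeMatrix:
    mat = rng.binomial(2, np.asarray(mafs, dtype=float), size=(n, len(mafs))).astype(float)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(len(snp_ids))]
    info = pd.DataFrame(
        {
            "chrom": [str(1 + i % 22) for i in range(len(snp_ids))],
            "allele_minor": [p[0] for p in pairs],
            "allele_major": [p[1] for p in pairs],
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")
    dosages = pd.DataFrame(mat, index=idx, columns=pd.Index(snp_ids, name="snp_id"))
    return GenotypeMatrix(dosages=dosages, snp_info=info)


def _calibrate_t2d_intercept(glucose: np.ndarray, mean_glucose: float, prevalence: float) -> float:
    """Root-find the logistic intercept that hits the target prevalence."""
    if prevalence <= 0.0:
        return -np.inf
    if prevalence >= 1.0:
        return np.inf
    centered = T2D_GLUCOSE_SLOPE * (glucose - mean_glucose)

    def gap(c: float) -> float:
        return float(expit(c + centered).mean() - prevalence)

    return float(optimize.brentq(gap, -40.0, 40.0))


def _covariate_block(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    n = config.n_subjects
    sex = (rng.random(n) < config.prop_male).astype(int)  # 1 = male
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    p_diet = config.diet_mean / 14.0
    diet = np.clip(rng.binomial(14, p_diet, size=n), 0, 14)
    return pd.DataFrame({"sex": sex, "age": age, "bmi": bmi, "diet_score": diet})


def simulate_cohort(
    config: CohortConfig,
    snp_specs: Sequence[tuple[float, float]],
    seed: int,
    *,
    extra_glucose: np.ndarray | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> tuple[CohortTable, GroundTruth]:
    """Simulate one individual-level cohort.

    ``snp_specs`` is a list of (maf, beta_glucose) pairs: each SNP is drawn
    Binomial(2, MAF) under Hardy-Weinberg and contributes
    ``beta_glucose * dosage`` mg/dL to fasting glucose.  Gaussian noise is
    scaled so the marginal glucose SD matches ``config.glucose_sd`` (unless
    ``config.noise_sd`` overrides it); type 2 diabetes is assigned by a
    logistic model on glucose whose intercept is root-found so the realized
    expected prevalence matches the configured one.

    ``extra_glucose``/``genotypes`` are hooks used by
    :func:`simulate_two_sample` to inject a latent-exposure contribution;
    ordinary callers leave them unset.
    """
    rng_geno, rng_pheno = _split_seed(seed, 2)
    n = config.n_subjects
    mafs = [s[0] for s in snp_specs]
    betas = np.array([s[1] for s in snp_specs], dtype=float)
    if any(not (0.0 < m <= 0.5) for m in mafs):
        raise ValueError("SNP MAFs must lie in (0, 0.5]")

    if genotypes is None:
        snp_ids = [f"rs{900000 + i}" for i in range(len(snp_specs))]
        genotypes = _simulate_genotypes(rng_geno, n, mafs, snp_ids)
    else:
        snp_ids = genotypes.snp_ids
    dos = genotypes.dosages.to_numpy(dtype=float)

    cov = _covariate_block(rng_pheno, config)

    deterministic = (
        SEX_EFFECT * cov["sex"].to_numpy()
        + AGE_EFFECT * (cov["age"].to_numpy() - config.age_mean)
        + BMI_EFFECT * (cov["bmi"].to_numpy() - config.bmi_mean)
    )
    if len(snp_specs) > 0:
        deterministic = deterministic + dos @ betas
    if extra_glucose is not None:
        deterministic = deterministic + extra_glucose

    # variance budget: genetic + covariate + injected variance is subtracted
    # from the marginal target, the remainder is i.i.d. noise
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
    else:
        var_det = float(np.var(deterministic))
        var_noise = config.glucose_sd**2 - var_det
        if var_noise < 0:
            raise ValueError(
                "configured glucose_sd is smaller than the SD already "
                "implied by genetic + covariate effects"
            )
        noise_sd = float(np.sqrt(var_noise))

    intercept = config.glucose_mean - float(np.mean(deterministic))
    glucose = intercept + deterministic + rng_pheno.normal(0.0, noise_sd, size=n)

    c = _calibrate_t2d_intercept(glucose, config.glucose_mean, config.t2d_prevalence)
    p_t2d = expit(c + T2D_GLUCOSE_SLOPE * (glucose - config.glucose_mean))
    t2d = (rng_pheno.random(n) < p_t2d).astype(int)
    medication = ((rng_pheno.random(n) < config.medication_rate_in_t2d) & (t2d == 1)).astype(int)

    phen = cov.copy()
    phen.index = genotypes.dosages.index
    phen["glucose"] = glucose
    phen["t2d"] = t2d
    phen["medication"] = medication
    phen["diet_high"] = (phen["diet_score"] >= config.diet_high_cutoff).astype(int)

    truth = GroundTruth(
        seed=int(seed),
        snp_ids=tuple(snp_ids),
        maf=tuple(float(m) for m in mafs),
        beta_glucose=tuple(float(b) for b in betas),
    )
    return CohortTable(phenotypes=phen, genotypes=genotypes), truth


def simulate_two_sample(
    config: InstrumentConfig,
    cohort_config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortTable, GroundTruth]:
    """Simulate a full two-sample MR dataset with known causal effect.

    Sample 1 (exposure): per-SNP summary statistics whose estimated betas
    are drawn ``Normal(alpha_j, se_xj)`` with ``se_xj`` the analytic OLS
    slope SE at ``n_sample1`` and the SNP's MAF, the exposure being a latent
    microbial-trait abundance standardized to SD 1.

    Sample 2 (outcome): an individual-level cohort whose glucose includes
    ``theta_true * exposure`` plus any per-SNP direct (pleiotropic) effects.
    The two samples share SNP identities and alleles but no individuals —
    all random streams are split from the single master seed.

    Returns ``(exposure_stats, cohort, truth)``; outcome summary statistics
    are estimated from the cohort with
    :func:`micromr.assoc_screen.outcome_summary_stats`.
    """
    if cohort_config is None:
        cohort_config = CohortConfig()
    rng_s1, rng_design, rng_cohort_seed = _split_seed(seed, 3)

    J = config.n_instruments
    mafs = rng_design.uniform(*config.maf_range, size=J)
    alphas = rng_design.uniform(*config.alpha_range, size=J)
    pleio = np.zeros(J)
    if config.pleiotropy_effects is not None:
        pleio = np.asarray(config.pleiotropy_effects, dtype=float)
    if config.outlier_index is not None:
        # direct effect whose sign opposes theta's pull on glucose
        direction = 1.0 if config.theta_true <= 0 else -1.0
        pleio = pleio.copy()
        pleio[config.outlier_index] += direction * config.outlier_effect

    snp_ids = [f"rs{100000 + i}" for i in range(J)]
    var_g = 2.0 * mafs * (1.0 - mafs)
    explained = float(np.sum(alphas**2 * var_g))
    if explained >= 1.0:
        raise ValueError(
            "instrument effects explain >= 100% of the exposure variance; "
            "shrink alpha_range or n_instruments"
        )
    eps_var = 1.0 - explained  # latent exposure has unit variance by design

    # sample 1: analytic OLS slope SE at n1; residual variance of the
    # exposure given one SNP is 1 - alpha_j^2 * var_gj
    resid_var = 1.0 - alphas**2 * var_g
    se_x = np.sqrt(resid_var / (config.n_sample1 * var_g))
    beta_x_hat = rng_s1.normal(alphas, se_x)
    z = beta_x_hat / se_x
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(J)]
    exposure = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": [str(1 + i % 22) for i in range(J)],
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "eaf": mafs,
            "beta": beta_x_hat,
            "se": se_x,
            "pvalue": pvals,
            "n": config.n_sample1,
            "trait": "microbial_trait",
        }
    )

    # sample 2: genotypes, latent exposure, glucose
    cohort_seed = int(rng_cohort_seed.integers(0, 2**31 - 1))
    rng_geno, rng_expo = _split_seed(cohort_seed, 2)
    genotypes = _simulate_genotypes(rng_geno, cohort_config.n_subjects, mafs, snp_ids)
    dos = genotypes.dosages.to_numpy(dtype=float)
    latent = dos @ alphas + rng_expo.normal(0.0, np.sqrt(eps_var), size=cohort_config.n_subjects)
    extra = config.theta_true * latent + dos @ pleio

    cohort, _ = simulate_cohort(
        cohort_config,
        [(float(m), 0.0) for m in mafs],
        seed=cohort_seed + 1,
        extra_glucose=extra,
        genotypes=genotypes,
    )

    truth = GroundTruth(
        seed=int(seed),
        theta_true=float(config.theta_true),
        snp_ids=tuple(snp_ids),
        maf=tuple(float(m) for m in mafs),
        alpha=tuple(float(a) for a in alphas),
        pleiotropy=tuple(float(p) for p in pleio),
    )
    return exposure, cohort, truth
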