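"""Two-sample Mendelian randomization estimators.

Given J harmonized instruments (per-SNP exposure effect ``beta_x`` with SE
``se_x`` and outcome effect ``beta_y`` with SE ``se_y``), the battery
estimates the causal effect theta of the exposure on the outcome:

* Wald ratio — per-SNP ``beta_y / beta_x`` with a delta-method SE;
* IVW — inverse-variance-weighted regression of beta_y on beta_x through
  the origin (weights ``1/se_y^2``), with penalized, robust and
  penalized-robust variants;
* median family — simple / weighted / penalized-weighted median of the
  ratio estimates, SE by parametric bootstrap;
* MR-Egger — the same weighted regression with an unconstrained intercept;
  a non-zero intercept measures average directional pleiotropy.

All estimators are scikit-learn style: construct with hyper-parameters,
``fit(X)`` on an instrument table, read trailing-underscore attributes.
``X`` may be the DataFrame produced by
:func:`micromr.instruments.harmonize_all` or any array-like with columns
(beta_x, se_x, beta_y, se_y).

SEs for IVW and Egger use a multiplicative random-effects model: the
fixed-effect SE is scaled by the residual dispersion, floored at 1, so
between-instrument heterogeneity widens but never narrows the interval.
p-values are two-sided standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "IVWEstimator",
    "EggerRegression",
    "MedianRatioEstimator",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "median_estimator",
    "heterogeneity",
    "run_all_methods",
    "confidence_interval",
    "METHOD_ORDER",
]

Z975 = float(stats.norm.ppf(0.975))

#: Row order of the full method battery in the output table.
METHOD_ORDER = [
    "simple_median",
    "weighted_median",
    "penalized_weighted_median",
    "ivw",
    "penalized_ivw",
    "robust_ivw",
    "penalized_robust_ivw",
    "mr_egger",
    "penalized_mr_egger",
    "robust_mr_egger",
    "penalized_robust_mr_egger",
]


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_instruments: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pvalue": self.intercept_pvalue,
            "n_instruments": self.n_instruments,
        }


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q (IVW) or Rucker's Q' (Egger) heterogeneity test."""

    method: str  # 'ivw_q' or 'egger_q'
    Q: float
    df: int
    pvalue: float
    contributions: tuple[float, ...]


def confidence_interval(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal-theory CI: estimate +/- z * se."""
    if se < 0:
        raise ValueError("se must be non-negative")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return estimate - z * se, estimate + z * se


def _normal_p(estimate: float, se: float) -> float:
    if se == 0:
        return 0.0 if estimate != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(estimate) / se))


def _as_arrays(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coerce an instrument table to (beta_x, se_x, beta_y, se_y) arrays."""
    if isinstance(X, pd.DataFrame):
        cols = ["beta_x", "se_x", "beta_y", "se_y"]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"instrument table lacks columns {missing}")
        arr = X[cols].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("X must be (J, 4): beta_x, se_x, beta_y, se_y")
    if arr.shape[0] < 1:
        raise ValueError("at least one instrument required")
    bx, sx, by, sy = arr.T
    if (sx <= 0).any() or (sy <= 0).any():
        raise ValueError("instrument SEs must be positive")
    if (bx == 0).any():
        raise ValueError("beta_x must be non-zero for ratio-based estimation")
    return bx, sx, by, sy


def wald_ratio(
    beta_x: float,
    beta_y: float,
    se_y: float,
    se_x: float | None = None,
    second_order: bool = False,
) -> tuple[float, float]:
    """Per-instrument ratio estimate ``beta_y / beta_x`` and its SE.

    First-order delta method: ``se = se_y / |beta_x|``.  The second-order
    option adds the exposure-uncertainty term
    ``beta_y^2 * se_x^2 / beta_x^4`` under the radical.
    """
    if beta_x == 0:
        raise ValueError("beta_x must be non-zero")
    theta = beta_y / beta_x
    if second_order:
        if se_x is None:
            raise ValueError("second-order SE needs se_x")
        var = se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4
        return float(theta), float(np.sqrt(var))
    return float(theta), float(se_y / abs(beta_x))


def _penalized_weights(
    theta: np.ndarray, w: np.ndarray, theta_hat: float, penalty: float
) -> np.ndarray:
    """Down-weight instruments with heterogeneous ratio estimates.

    Each instrument's Cochran-Q contribution is referred to chi2_1; weight
    j is multiplied by ``min(1, penalty * p_j)``.
    """
    q_contrib = w * (theta - theta_hat) ** 2
    pvals = stats.chi2.sf(q_contrib, df=1)
    return w * np.minimum(1.0, penalty * pvals)


def _robust_origin_fit(bx, by, w, max_iter, tol):
    """Tukey-biweight robust fit of by on bx through the origin.

    Iteratively reweighted M-estimation on the 1/se_y^2-weighted problem,
    started from the weighted-LS solution; Huber fallback when the
    redescending fit fails to converge.
    """
    xs = np.sqrt(w) * bx
    ys = np.sqrt(w) * by
    # default start is WLS on the pre-weighted data == the weighted-LS fit
    for norm in (sm.robust.norms.TukeyBiweight(c=4.685), sm.robust.norms.HuberT()):
        try:
            res = sm.RLM(ys, xs[:, None], M=norm).fit(maxiter=max_iter, tol=tol)
            if np.isfinite(res.params[0]) and np.isfinite(res.bse[0]):
                return float(res.params[0]), float(res.bse[0]), float(res.scale)
        except Exception:
            continue
    raise RuntimeError("robust fit failed to converge")


def _robust_intercept_fit(bx, by, w, max_iter, tol):
    """Tukey-biweight robust fit of by on bx with intercept (Egger)."""
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * bx])  # weighted intercept column
    ys = sw * by
    for norm in (sm.robust.norms.TukeyBiweight(c=4.685), sm.robust.norms.HuberT()):
        try:
            res = sm.RLM(ys, X, M=norm).fit(maxiter=max_iter, tol=tol)
            if np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse)):
                return res.params, res.bse, float(res.scale)
        except Exception:
            continue
    raise RuntimeError("robust fit failed to converge")


class _BaseMR(BaseEstimator):
    """Shared fit plumbing for the MR estimator family."""

    def fit(self, X, y=None):
        bx, sx, by, sy = _as_arrays(X)
        self.n_instruments_ = int(bx.size)
        self._fit(bx, sx, by, sy)
        self.ci_ = confidence_interval(self.estimate_, self.se_)
        self.pvalue_ = _normal_p(self.estimate_, self.se_)
        return self

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_estimate(self, method: str | None = None) -> MREstimate:
        return MREstimate(
            method=method or self.method_,
            estimate=float(self.estimate_),
            se=float(self.se_),
            ci_low=float(self.ci_[0]),
            ci_high=float(self.ci_[1]),
            pvalue=float(self.pvalue_),
            n_instruments=self.n_instruments_,
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_pvalue=getattr(self, "intercept_pvalue_", None),
        )


class IVWEstimator(_BaseMR):
    """Inverse-variance-weighted causal-effect estimator.

    Parameters
    ----------
    penalized : bool
        Down-weight heterogeneous instruments via their chi2_1 Q-contribution
        p-values (weight *= min(1, penalty_constant * p)).
    robust : bool
        Replace weighted least squares with Tukey-biweight robust regression
        (c = 4.685, Huber fallback).
    fixed_effect : bool
        Skip the multiplicative random-effects SE scaling (dispersion floor
        at 1 otherwise).

    Attributes (after fit)
    ----------------------
    estimate_, se_, ci_, pvalue_ : the causal effect theta and inference.
    sigma_ : residual dispersion (sqrt of the scaled residual variance).
    weights_ : final per-instrument weights on the ratio scale.
    """

    method_ = "ivw"

    def __init__(
        self,
        penalized: bool = False,
        robust: bool = False,
        fixed_effect: bool = False,
        penalty_constant: float = 20.0,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.penalized = penalized
        self.robust = robust
        self.fixed_effect = fixed_effect
        self.penalty_constant = penalty_constant
        self.max_iter = max_iter
        self.tol = tol

    def _fit(self, bx, sx, by, sy):
        J = bx.size
        if J == 1:
            self.estimate_, self.se_ = wald_ratio(bx[0], by[0], sy[0])
            self.sigma_ = 1.0
            self.weights_ = np.array([1.0 / (sy[0] / abs(bx[0])) ** 2])
            return
        # ratio form: theta_j with weights 1/se(theta_j)^2 is identical to
        # the regression of by on bx through the origin with weights 1/sy^2
        theta = by / bx
        w = (bx / sy) ** 2
        theta_fe = float(np.sum(w * theta) / np.sum(w))
        if self.penalized:
            w = _penalized_weights(theta, w, theta_fe, self.penalty_constant)
            if not (w > 0).any():
                raise ValueError("all instrument weights vanished under penalization")
        if self.robust:
            # regression form: weights 1/sy^2 (= ratio weights / bx^2)
            est, se_rob, scale = _robust_origin_fit(bx, by, w / bx**2, self.max_iter, self.tol)
            self.estimate_ = est
            sigma = max(1.0, scale) if not self.fixed_effect else 1.0
            base_se = 1.0 / np.sqrt(np.sum(w))
            self.se_ = float(max(se_rob, base_se) if not self.fixed_effect else se_rob)
            self.sigma_ = float(sigma)
            self.weights_ = w
            return
        est = float(np.sum(w * theta) / np.sum(w))
        resid_disp = float(np.sum(w * (theta - est) ** 2) / (J - 1))
        sigma = 1.0 if self.fixed_effect else max(1.0, np.sqrt(resid_disp))
        self.estimate_ = est
        self.se_ = float(sigma / np.sqrt(np.sum(w)))
        self.sigma_ = float(sigma)
        self.weights_ = w

    def predict(self, beta_x):
        """Predicted outcome effects theta * beta_x for given exposure effects."""
        return np.asarray(beta_x, dtype=float) * self.estimate_


class EggerRegression(_BaseMR):
    """MR-Egger: weighted regression of beta_y on beta_x with intercept.

    The slope is the causal estimate; the intercept estimates average
    directional pleiotropy and its p-value is the Egger pleiotropy test.
    Requires instruments oriented so beta_x >= 0 (the fit is not invariant
    to per-SNP allele re-orientation).  With ``fit_intercept=False`` the
    model collapses to IVW exactly.
    """

    method_ = "mr_egger"

    def __init__(
        self,
        penalized: bool = False,
        robust: bool = False,
        fixed_effect: bool = False,
        fit_intercept: bool = True,
        penalty_constant: float = 20.0,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.penalized = penalized
        self.robust = robust
        self.fixed_effect = fixed_effect
        self.fit_intercept = fit_intercept
        self.penalty_constant = penalty_constant
        self.max_iter = max_iter
        self.tol = tol

    def _fit(self, bx, sx, by, sy):
        J = bx.size
        if not self.fit_intercept:
            inner = IVWEstimator(
                penalized=self.penalized,
                robust=self.robust,
                fixed_effect=self.fixed_effect,
                penalty_constant=self.penalty_constant,
            ).fit(np.column_stack([bx, sx, by, sy]))
            self.estimate_, self.se_ = inner.estimate_, inner.se_
            self.sigma_ = inner.sigma_
            self.weights_ = inner.weights_
            self.intercept_ = 0.0
            self.intercept_se_ = 0.0
            self.intercept_pvalue_ = 1.0
            return
        if J < 3:
            raise ValueError("MR-Egger needs at least 3 instruments")
        if (bx < 0).any():
            raise ValueError("MR-Egger requires beta_x >= 0 (harmonize first)")
        w = 1.0 / sy**2
        if self.penalized:
            # penalize on Rucker residuals from the plain Egger fit
            a0, b0 = self._wls(bx, by, w)
            q_contrib = w * (by - a0 - b0 * bx) ** 2
            pvals = stats.chi2.sf(q_contrib, df=1)
            w = w * np.minimum(1.0, self.penalty_constant * pvals)
            if not (w > 0).any():
                raise ValueError("all instrument weights vanished under penalization")
        if self.robust:
            params, bse, scale = _robust_intercept_fit(bx, by, w, self.max_iter, self.tol)
            a, b = float(params[0]), float(params[1])
            se_a, se_b = float(bse[0]), float(bse[1])
            if not self.fixed_effect:
                # floor at the fixed-effect SEs of the weighted design
                se_fe = self._fe_ses(bx, w)
                se_a, se_b = max(se_a, se_fe[0]), max(se_b, se_fe[1])
            sigma = max(1.0, scale)
        else:
            a, b = self._wls(bx, by, w)
            resid = by - a - b * bx
            disp = float(np.sum(w * resid**2) / (J - 2))
            sigma = 1.0 if self.fixed_effect else max(1.0, np.sqrt(disp))
            se_fe = self._fe_ses(bx, w)
            se_a, se_b = sigma * se_fe[0], sigma * se_fe[1]
        self.estimate_ = float(b)
        self.se_ = float(se_b)
        self.sigma_ = float(sigma)
        self.weights_ = w
        self.intercept_ = float(a)
        self.intercept_se_ = float(se_a)
        ci = confidence_interval(self.intercept_, self.intercept_se_)
        self.intercept_ci_ = ci
        self.intercept_pvalue_ = _normal_p(self.intercept_, self.intercept_se_)

    @staticmethod
    def _wls(bx, by, w):
        sw = np.sum(w)
        xbar = np.sum(w * bx) / sw
        ybar = np.sum(w * by) / sw
        sxx = np.sum(w * (bx - xbar) ** 2)
        if sxx == 0:
            raise ValueError("exposure effects have no spread; Egger slope unidentified")
        b = float(np.sum(w * (bx - xbar) * (by - ybar)) / sxx)
        a = float(ybar - b * xbar)
        return a, b

    @staticmethod
    def _fe_ses(bx, w):
        sw = np.sum(w)
        xbar = np.sum(w * bx) / sw
        sxx = np.sum(w * (bx - xbar) ** 2)
        se_b = 1.0 / np.sqrt(sxx)
        se_a = np.sqrt(1.0 / sw + xbar**2 / sxx)
        return se_a, se_b


class MedianRatioEstimator(_BaseMR):
    """Median-of-ratios causal estimator (simple / weighted / penalized).

    The weighted median interpolates the weighted empirical distribution of
    the per-SNP ratio estimates at probability 0.5; it is consistent when
    instruments carrying at least half the weight are valid.  SE by seeded
    parametric bootstrap: beta_x and beta_y are resampled from
    Normal(estimate, SE) and the median recomputed.
    """

    def __init__(
        self,
        weighting: str = "weighted",
        n_boot: int = 5000,
        random_state: int | None = None,
        penalty_constant: float = 20.0,
        min_boot: int = 100,
    ):
        self.weighting = weighting
        self.n_boot = n_boot
        self.random_state = random_state
        self.penalty_constant = penalty_constant
        self.min_boot = min_boot

    @property
    def method_(self) -> str:
        return {
            "simple": "simple_median",
            "weighted": "weighted_median",
            "penalized_weighted": "penalized_weighted_median",
        }[self.weighting]

    @staticmethod
    def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
        order = np.argsort(theta, kind="stable")
        t = theta[order]
        wn = w[order] / np.sum(w[order])
        s = np.cumsum(wn) - wn / 2.0
        return float(np.interp(0.5, s, t))

    def _weights(self, theta, w_ratio):
        if self.weighting == "simple":
            return np.full_like(theta, 1.0 / theta.size)
        if self.weighting == "weighted":
            return w_ratio
        if self.weighting == "penalized_weighted":
            theta_ivw = float(np.sum(w_ratio * theta) / np.sum(w_ratio))
            return _penalized_weights(theta, w_ratio, theta_ivw, self.penalty_constant)
        raise ValueError(f"unknown weighting {self.weighting!r}")

    def _fit(self, bx, sx, by, sy):
        if self.n_boot < self.min_boot:
            raise ValueError(
                f"n_boot={self.n_boot} below the minimum {self.min_boot}; "
                "raise n_boot or lower min_boot explicitly"
            )
        J = bx.size
        if J == 1:
            self.estimate_, self.se_ = wald_ratio(bx[0], by[0], sy[0])
            return
        theta = by / bx
        w_ratio = (bx / sy) ** 2
        w = self._weights(theta, w_ratio)
        self.estimate_ = self._weighted_median(theta, w)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            ok = bxs != 0
            th = bys[ok] / bxs[ok]
            wr = (bxs[ok] / sy[ok]) ** 2
            boots[b] = self._weighted_median(th, self._weights(th, wr))
        self.se_ = float(np.std(boots, ddof=1))


# ---------------------------------------------------------------------------
# functional façade


def _fit_safe(est: _BaseMR, X, method: str) -> MREstimate:
    try:
        return est.fit(X).to_estimate(method)
    except Exception:
        nan = float("nan")
        return MREstimate(method, nan, nan, nan, nan, nan, 0)


def ivw(insts, penalized: bool = False, robust: bool = False, **kw) -> MREstimate:
    """Inverse-variance-weighted estimate (see :class:`IVWEstimator`)."""
    name = ("penalized_" if penalized else "") + ("robust_" if robust else "") + "ivw"
    return IVWEstimator(penalized=penalized, robust=robust, **kw).fit(insts).to_estimate(name)


def mr_egger(insts, penalized: bool = False, robust: bool = False, **kw) -> MREstimate:
    """MR-Egger slope + intercept (see :class:`EggerRegression`)."""
    name = ("penalized_" if penalized else "") + ("robust_" if robust else "") + "mr_egger"
    return EggerRegression(penalized=penalized, robust=robust, **kw).fit(insts).to_estimate(name)


def median_estimator(
    insts, weighting: str = "weighted", n_boot: int = 5000, seed: int | None = None, **kw
) -> MREstimate:
    """Median-family estimate (see :class:`MedianRatioEstimator`)."""
    est = MedianRatioEstimator(weighting=weighting, n_boot=n_boot, random_state=seed, **kw)
    return est.fit(insts).to_estimate()


def heterogeneity(insts, fitted: MREstimate | _BaseMR) -> HeterogeneityResult:
    """Cochran's Q about an IVW fit, or Rucker's Q' about an Egger fit.

    IVW: ``Q = sum_j w_j (theta_j - theta_hat)^2`` with ratio weights
    ``w_j = (beta_x/se_y)^2`` and J-1 df.  Egger: weighted squared
    residuals about the line with J-2 df.
    """
    bx, sx, by, sy = _as_arrays(insts)
    J = bx.size
    if isinstance(fitted, _BaseMR):
        fitted = fitted.to_estimate()
    is_egger = "egger" in fitted.method
    if is_egger:
        df = J - 2
        a = fitted.intercept if fitted.intercept is not None else 0.0
        contrib = (by - a - fitted.estimate * bx) ** 2 / sy**2
        name = "egger_q"
    else:
        df = J - 1
        theta = by / bx
        w = (bx / sy) ** 2
        contrib = w * (theta - fitted.estimate) ** 2
        name = "ivw_q"
    if df <= 0:
        raise ValueError("not enough instruments for a heterogeneity test")
    Q = float(contrib.sum())
    return HeterogeneityResult(
        method=name,
        Q=Q,
        df=df,
        pvalue=float(stats.chi2.sf(Q, df)),
        contributions=tuple(float(c) for c in contrib),
    )


def run_all_methods(insts, seed: int | None = None, n_boot: int = 5000) -> pd.DataFrame:
    """Fit the full eleven-method battery and return one row per method.

    Rows follow :data:`METHOD_ORDER`; Egger rows carry the intercept
    triple.  A single instrument collapses every method to the Wald ratio.
    Per-method failures yield a ``failed`` status row rather than aborting.
    """
    bx, sx, by, sy = _as_arrays(insts)
    rows = []
    if bx.size == 1:
        est, se = wald_ratio(bx[0], by[0], sy[0])
        lo, hi = confidence_interval(est, se)
        p = _normal_p(est, se)
        for m in METHOD_ORDER:
            rows.append(
                MREstimate(m, est, se, lo, hi, p, 1).to_row() | {"status": "ok"}
            )
        return pd.DataFrame(rows)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    med_seeds = {
        w: int(s.generate_state(1)[0] % (2**31))
        for w, s in zip(("simple", "weighted", "penalized_weighted"), ss.spawn(3))
    }

    specs: list[tuple[str, _BaseMR]] = [
        ("simple_median", MedianRatioEstimator("simple", n_boot, med_seeds["simple"])),
        ("weighted_median", MedianRatioEstimator("weighted", n_boot, med_seeds["weighted"])),
        (
            "penalized_weighted_median",
            MedianRatioEstimator("penalized_weighted", n_boot, med_seeds["penalized_weighted"]),
        ),
        ("ivw", IVWEstimator()),
        ("penalized_ivw", IVWEstimator(penalized=True)),
        ("robust_ivw", IVWEstimator(robust=True)),
        ("penalized_robust_ivw", IVWEstimator(penalized=True, robust=True)),
        ("mr_egger", EggerRegression()),
        ("penalized_mr_egger", EggerRegression(penalized=True)),
        ("robust_mr_egger", EggerRegression(robust=True)),
        ("penalized_robust_mr_egger", EggerRegression(penalized=True, robust=True)),
    ]
    for name, est in specs:
        res = _fit_safe(est, insts, name)
        rows.append(res.to_row() | {"status": "failed" if np.isnan(res.estimate) else "ok"})
    return pd.DataFrame(rows)


def scatter_data(insts, methods: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-SNP effect pairs with error bars, plot-ready.

    Mirrors the scatter figures of an MR report: beta_x vs beta_y with
    1.96*SE bars; per-method slopes (and Egger intercepts) can be joined
    from the ``methods`` table by the caller.
    """
    bx, sx, by, sy = _as_arrays(insts)
    df = pd.DataFrame(
        {
            "beta_x": bx,
            "se_x": sx,
            "beta_y": by,
            "se_y": sy,
            "beta_x_low": bx - Z975 * sx,
            "beta_x_high": bx + Z975 * sx,
            "beta_y_low": by - Z975 * sy,
            "beta_y_high": by + Z975 * sy,
        }
    )
    if isinstance(insts, pd.DataFrame) and "snp_id" in insts.columns:
        df.insert(0, "snp_id", insts["snp_id"].to_numpy())
    return df
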