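"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a harmonized :class:`~bimr.summary_data.InstrumentSet`
and return effects on the log-odds-ratio-per-log-odds-ratio scale, with an
odds-ratio transform attached. Five methods are provided:

* ``ivw`` — inverse-variance weighted combination of Wald ratios, the
  principal estimator, with fixed-effect or multiplicative random-effects
  standard errors;
* ``egger`` — weighted regression with an intercept; the slope corrects for
  directional pleiotropy under the InSIDE assumption and the intercept tests
  for it;
* ``weighted_median`` — consistent when instruments carrying at least half
  of the total weight are valid; parametric-bootstrap standard error;
* ``contamination_mixture`` — profile likelihood over a grid of candidate
  effects, modelling each Wald ratio as either valid (centred on the causal
  effect) or invalid (centred on zero with inflated variance);
* the degenerate single-instrument Wald ratio.

First-order weights (outcome standard errors only) are used throughout,
matching the Wald-ratio standard error definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_data import HarmonizedInstrument, InstrumentSet

__all__ = [
    "MREstimate",
    "EggerResult",
    "ConMixResult",
    "ivw",
    "egger",
    "weighted_median",
    "contamination_mixture",
]

Z975 = stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-OR scale with its OR transform."""

    method: str
    theta: float
    se: float | None
    ci_low: float
    ci_high: float
    pvalue: float | None
    n_snps: int

    def __post_init__(self):
        if self.ci_low > self.theta or self.theta > self.ci_high:
            raise ValueError("confidence interval must contain the point estimate")

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(odds ratio, CI low, CI high) per 1-unit increase in log-OR of the exposure."""
        return (float(np.exp(self.theta)), float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))

    def to_dict(self) -> dict:
        or_, lo, hi = self.or_scale
        return {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
            "odds_ratio": or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
        }


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    residual_q: float

    def to_dict(self) -> dict:
        d = self.slope.to_dict()
        d.update({
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pvalue": self.intercept_pvalue,
            "residual_q": self.residual_q,
        })
        return d


@dataclass(frozen=True)
class ConMixResult:
    """Contamination-mixture output: grid maximizer, likelihood-based CI set,
    and the per-instrument valid/invalid classification at the maximizer."""

    theta_hat: float
    ci_set: tuple[tuple[float, float], ...]
    psi: float
    valid_flags: tuple[bool, ...]
    estimate: MREstimate

    def __post_init__(self):
        if not self.ci_set:
            raise ValueError("ci_set must be non-empty")
        if not any(lo <= self.theta_hat <= hi for lo, hi in self.ci_set):
            raise ValueError("theta_hat must lie inside the CI set")


def _arrays(iset: InstrumentSet | Sequence[HarmonizedInstrument]):
    instruments = list(iset)
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    ratio = np.array([i.wald_ratio for i in instruments])
    ratio_se = np.array([i.wald_se for i in instruments])
    return bx, by, sy, ratio, ratio_se


def ivw(iset: InstrumentSet | Sequence[HarmonizedInstrument], model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate of the causal effect.

    Weights are (beta_exposure/se_outcome)^2, equivalent to a weighted
    regression of outcome betas on exposure betas through the origin. The
    random-effects model inflates the fixed-effect SE by
    max(1, sqrt(Q/(J-1))) where Q is Cochran's Q at the estimate.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, by, sy, ratio, ratio_se = _arrays(iset)
    j = len(ratio)
    if j == 0:
        raise EstimationError("ivw requires at least one instrument")
    w = (bx / sy) ** 2
    if not np.any(w > 0):
        raise EstimationError("all IVW weights are zero")
    theta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if j == 1:
        warnings.warn("single instrument: IVW degenerates to the Wald ratio", stacklevel=2)
        se = se_fixed
        method = "wald"
    else:
        q = float(np.sum(w * (ratio - theta) ** 2))
        scale = max(1.0, np.sqrt(q / (j - 1))) if model == "random" else 1.0
        se = se_fixed * scale
        method = f"ivw_{model}"
    p = float(2 * stats.norm.sf(abs(theta) / se))
    return MREstimate(method, theta, se, theta - Z975 * se, theta + Z975 * se, p, j)


def egger(iset: InstrumentSet | Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger regression: weighted fit of outcome on exposure betas with intercept.

    Instruments are first oriented so every exposure beta is positive. The
    intercept estimates the average directional pleiotropic effect; its
    two-sided t-test (J-2 df) is the pleiotropy test. Standard errors carry
    a multiplicative overdispersion factor floored at 1.
    """
    bx, by, sy, *_ = _arrays(iset)
    j = len(bx)
    if j < 3:
        raise EstimationError(f"egger requires at least 3 instruments, got {j}")
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sy**2

    # Weighted least squares y ~ a + b x via normal equations.
    X = np.column_stack([np.ones(j), x])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (j - 2))
    ses = np.sqrt(np.diag(cov_unscaled) * phi)

    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(ses[0]), float(ses[1])
    tdist = stats.t(df=j - 2)
    p_slope = float(2 * tdist.sf(abs(slope) / se_slope))
    p_int = float(2 * tdist.sf(abs(intercept) / se_int))
    tcrit = float(tdist.ppf(0.975))
    est = MREstimate(
        "egger", slope, se_slope,
        slope - tcrit * se_slope, slope + tcrit * se_slope, p_slope, j,
    )
    return EggerResult(est, intercept, se_int, p_int, q)


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2  # midpoint cumulative weights
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5))
    # linear interpolation between the bracketing sorted ratios
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(
    iset: InstrumentSet | Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 42,
) -> MREstimate:
    """Weighted median of the Wald ratios with a parametric-bootstrap SE.

    The estimate interpolates the inverse-variance-weighted cumulative
    distribution of sorted ratios at weight 0.5; it is consistent when valid
    instruments contribute at least half the total weight. The SE is the
    standard deviation of the estimate over ``n_boot`` replicates with each
    ratio redrawn from Normal(ratio, wald_se^2).
    """
    *_, ratio, ratio_se = _arrays(iset)
    j = len(ratio)
    if j < 3:
        raise EstimationError(f"weighted_median requires at least 3 instruments, got {j}")
    if n_boot < 100:
        raise EstimationError("n_boot must be >= 100")
    w = 1.0 / ratio_se**2
    theta = _weighted_median_point(ratio, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratio, ratio_se, size=(n_boot, j))
    boots = np.array([_weighted_median_point(d, w) for d in draws])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        p = None if theta == 0 else 0.0
        return MREstimate("weighted_median", theta, se, theta, theta, p, j)
    p = float(2 * stats.norm.sf(abs(theta) / se))
    return MREstimate("weighted_median", theta, se, theta - Z975 * se, theta + Z975 * se, p, j)


def contamination_mixture(
    iset: InstrumentSet | Sequence[HarmonizedInstrument],
    psi: float | str = "auto",
    grid: np.ndarray | None = None,
) -> ConMixResult:
    """Contamination-mixture estimate by profile likelihood over a grid.

    At each candidate effect theta, every instrument contributes the larger
    of its valid-component log-likelihood Normal(ratio; theta, wald_se^2)
    and its invalid-component log-likelihood Normal(ratio; 0, wald_se^2 +
    psi^2). The estimate maximizes the summed profile; the confidence set
    collects grid values within a chi-squared(1) half-deviance (3.84) of the
    maximum and may be disconnected. ``psi="auto"`` uses 1.5 times the SD of
    the ratio estimates.
    """
    *_, ratio, ratio_se = _arrays(iset)
    j = len(ratio)
    if j < 2:
        raise EstimationError(f"contamination_mixture requires at least 2 instruments, got {j}")
    if psi == "auto":
        psi_val = 1.5 * float(np.std(ratio, ddof=1))
        if psi_val == 0:
            psi_val = float(np.mean(ratio_se))  # degenerate: all ratios identical
    else:
        psi_val = float(psi)
        if psi_val <= 0:
            raise EstimationError("psi must be positive")

    # Random-effects SE so the default grid stays wide under heterogeneity.
    ivw_est = ivw(iset, model="random") if j > 1 else None
    if grid is None:
        center, half = ivw_est.theta, 10 * ivw_est.se
        grid = np.linspace(center - half, center + half, 2001)
    else:
        grid = np.asarray(grid, dtype=float)
        if ivw_est is not None and not (grid.min() <= ivw_est.theta <= grid.max()):
            warnings.warn(
                "grid does not cover the IVW estimate; consider a wider grid", stacklevel=2
            )

    ll_valid = stats.norm.logpdf(ratio[None, :], loc=grid[:, None], scale=ratio_se[None, :])
    inv_sd = np.sqrt(ratio_se**2 + psi_val**2)
    ll_invalid = stats.norm.logpdf(ratio, loc=0.0, scale=inv_sd)[None, :]
    per_snp = np.maximum(ll_valid, ll_invalid)
    profile = per_snp.sum(axis=1)

    imax = int(np.argmax(profile))
    theta_hat = float(grid[imax])
    in_set = 2 * (profile[imax] - profile) <= stats.chi2.ppf(0.95, df=1)
    intervals = _runs_to_intervals(grid, in_set)
    valid_flags = tuple(bool(v) for v in (ll_valid[imax] >= ll_invalid[0]))

    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    est = MREstimate("contamination_mixture", theta_hat, None, lo, hi, None, j)
    return ConMixResult(theta_hat, intervals, psi_val, valid_flags, est)


def _runs_to_intervals(grid: np.ndarray, mask: np.ndarray) -> tuple[tuple[float, float], ...]:
    intervals = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    return tuple(intervals)
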