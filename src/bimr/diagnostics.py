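"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures the dispersion of per-instrument Wald ratios around the
pooled estimate; excess Q signals heterogeneity, which in MR usually means
horizontal pleiotropy. MR-PRESSO turns the same residual sum of squares into
a simulation-calibrated global test, flags individual outlying instruments,
and checks (distortion test) whether removing them materially changes the
causal estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import EstimationError, ivw
from .summary_data import HarmonizedInstrument, InstrumentSet

__all__ = ["HeterogeneityResult", "PressoResult", "cochran_q", "mr_presso"]


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    pvalue: float

    def to_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "pvalue": self.pvalue}


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results.

    ``theta_raw``/``theta_corrected`` are IVW estimates before/after
    removing flagged outliers; ``distortion_pvalue`` is None when no outlier
    was flagged.
    """

    global_rss: float
    global_pvalue: float
    outlier_indices: tuple[int, ...]
    outlier_variant_ids: tuple[str, ...]
    outlier_pvalues: tuple[float, ...]
    distortion_pvalue: float | None
    theta_raw: float
    theta_corrected: float
    n_sim: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "global_rss": self.global_rss,
            "global_pvalue": self.global_pvalue,
            "outlier_indices": list(self.outlier_indices),
            "outlier_variant_ids": list(self.outlier_variant_ids),
            "outlier_pvalues": list(self.outlier_pvalues),
            "distortion_pvalue": self.distortion_pvalue,
            "theta_raw": self.theta_raw,
            "theta_corrected": self.theta_corrected,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _arrays(iset):
    instruments = list(iset)
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    ratio = np.array([i.wald_ratio for i in instruments])
    ratio_se = np.array([i.wald_se for i in instruments])
    ids = [i.variant_id for i in instruments]
    return bx, by, sy, ratio, ratio_se, ids


def cochran_q(
    iset: InstrumentSet | Sequence[HarmonizedInstrument],
    theta: float,
    df_reduction: int = 1,
) -> HeterogeneityResult:
    """Cochran's Q at a given pooled estimate.

    Q = sum over instruments of (ratio - theta)^2 / wald_se^2 with df = J -
    ``df_reduction`` (1 when theta is the IVW estimate, 2 for Egger
    residuals).
    """
    *_, ratio, ratio_se, _ids = _arrays(iset)
    j = len(ratio)
    if j < 2:
        raise EstimationError("cochran_q requires at least 2 instruments")
    w = 1.0 / ratio_se**2
    q = float(np.sum(w * (ratio - theta) ** 2))
    df = j - df_reduction
    if df < 1:
        raise EstimationError("degrees of freedom must be >= 1")
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q, df, p)


def _loo_ivw(ratio: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimate for each instrument."""
    sw, swr = np.sum(w), np.sum(w * ratio)
    return (swr - w * ratio) / (sw - w)


def mr_presso(
    iset: InstrumentSet | Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 42,
    outlier_alpha: float = 0.05,
    n_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO: global heterogeneity, per-instrument outlier, distortion tests.

    The observed statistic is the leave-one-out weighted residual sum of
    squares; its null distribution comes from ``n_sim`` parametric
    simulations with outcome betas redrawn around the leave-one-out fitted
    values. Per-instrument outlier p-values are Bonferroni-corrected over
    the number of instruments. The distortion test compares the relative
    change in the IVW estimate after outlier removal with the change under
    removal of random subsets of the same size. Empirical p-values use the
    (r+1)/(n+1) convention.
    """
    bx, by, sy, ratio, ratio_se, ids = _arrays(iset)
    j = len(ratio)
    if j < 4:
        raise EstimationError(f"mr_presso requires at least 4 instruments, got {j}")
    if n_sim < 500:
        raise EstimationError("n_sim must be >= 500")

    instruments = list(iset)
    w = 1.0 / ratio_se**2
    theta_loo = _loo_ivw(ratio, w)
    obs_resid = w * (ratio - theta_loo) ** 2
    rss_obs = float(np.sum(obs_resid))

    rng = np.random.default_rng(seed)
    # Null: Gamma*_j ~ Normal(theta_loo_j * gamma_j, sigma_Yj^2), same functional.
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    ratio_sim = by_sim / bx
    sw = np.sum(w)
    theta_loo_sim = (np.sum(w * ratio_sim, axis=1, keepdims=True) - w * ratio_sim) / (sw - w)
    resid_sim = w * (ratio_sim - theta_loo_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    per_snp_p = (np.sum(resid_sim >= obs_resid, axis=0) + 1) / (n_sim + 1)
    corrected = np.minimum(per_snp_p * j, 1.0)
    outliers = tuple(int(i) for i in np.flatnonzero(corrected < outlier_alpha))

    theta_raw = ivw(instruments, model="random").theta
    if outliers:
        keep = [inst for i, inst in enumerate(instruments) if i not in outliers]
        theta_corrected = ivw(keep, model="random").theta
        distortion_p = _distortion_test(
            ratio, w, len(outliers), theta_raw, theta_corrected, n_distortion, rng
        )
    else:
        theta_corrected = theta_raw
        distortion_p = None

    return PressoResult(
        global_rss=rss_obs,
        global_pvalue=global_p,
        outlier_indices=outliers,
        outlier_variant_ids=tuple(ids[i] for i in outliers),
        outlier_pvalues=tuple(float(p) for p in corrected),
        distortion_pvalue=distortion_p,
        theta_raw=float(theta_raw),
        theta_corrected=float(theta_corrected),
        n_sim=n_sim,
        seed=seed,
    )


def _distortion_test(
    ratio: np.ndarray,
    w: np.ndarray,
    n_out: int,
    theta_raw: float,
    theta_corrected: float,
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    j = len(ratio)
    if theta_corrected == 0:
        return 1.0
    obs = abs((theta_corrected - theta_raw) / theta_corrected)
    stats_sim = np.empty(n_draws)
    for b in range(n_draws):
        drop = rng.choice(j, size=n_out, replace=False)
        keep = np.setdiff1d(np.arange(j), drop)
        th = np.sum(w[keep] * ratio[keep]) / np.sum(w[keep])
        stats_sim[b] = abs((th - theta_raw) / th) if th != 0 else np.inf
    return float((np.sum(stats_sim >= obs) + 1) / (n_draws + 1))
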