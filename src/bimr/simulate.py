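"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the summary-level inputs of a bidirectional MR study
of two binary traits: per-variant effect estimates on the log-odds scale
from an exposure GWAS and an independent outcome GWAS. Each instrument j
has a true exposure effect gamma_j; its true outcome effect is
theta * gamma_j plus an optional pleiotropic direct effect alpha_j. The
standard error of a log-odds effect estimate at allele frequency ``maf`` in
a study of ``n`` individuals with case fraction ``K`` uses the logistic
score approximation

    sigma = 1 / sqrt(2 * maf * (1 - maf) * n * K * (1 - K))

so that the scenario sample sizes are interpretable as real case/non-case
counts. Pleiotropy modes: ``none``; ``balanced`` (alpha mean-zero);
``directional`` (alpha has non-zero mean — biases IVW, detected by the
Egger intercept); ``inside_violating`` (alpha correlated with gamma —
breaks the InSIDE assumption behind Egger).

The shipped scenario pack mirrors a published bidirectional depression /
reflux-disease design: 31 forward instruments against an outcome GWAS of
385,276 (80,265 cases), and 24 reverse instruments against an outcome GWAS
of 173,005 (59,851 cases).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .summary_data import VariantAssociation

__all__ = [
    "SyntheticTruth",
    "SCENARIOS",
    "scenario",
    "simulate_summary_arrays",
    "generate_two_sample",
]

# Non-palindromic allele pairs; strand is always resolvable, so no variant
# is lost to palindromic ambiguity unless palindromic_fraction > 0.
_SAFE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of one simulated two-sample dataset."""

    theta: float = 0.0                      # true causal effect, log-OR per log-OR
    n_snps: int = 31
    gamma_low: float = 0.05                 # uniform bounds on |true exposure effect|
    gamma_high: float = 0.15
    pleiotropy_mode: str = "none"           # none | balanced | directional | inside_violating
    alpha_mean: float = 0.0                 # pleiotropy location (directional)
    alpha_sd: float = 0.01                  # pleiotropy spread
    invalid_fraction: float = 0.0           # proportion of contaminated instruments
    n_exposure: int = 173_005
    n_outcome: int = 385_276
    case_fraction_exposure: float = 59_851 / 173_005
    case_fraction_outcome: float = 80_265 / 385_276
    maf_low: float = 0.1
    maf_high: float = 0.5
    palindromic_fraction: float = 0.0       # fraction of variants given A/T or C/G alleles
    ld_block_size: int = 1                  # >1 adds correlated blocks to the LD matrix
    ld_block_r2: float = 0.8
    seed: int = 42

    def __post_init__(self):
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 < self.maf_low <= self.maf_high < 1:
            raise ValueError("maf bounds must satisfy 0 < low <= high < 1")


#: Scenario pack mirroring the bidirectional depression/reflux design.
SCENARIOS: dict[str, SyntheticTruth] = {
    "mdd_to_gerd": SyntheticTruth(
        theta=float(np.log(1.31)),
        n_snps=31,
        n_exposure=173_005,
        case_fraction_exposure=59_851 / 173_005,
        n_outcome=385_276,
        case_fraction_outcome=80_265 / 385_276,
    ),
    "gerd_to_mdd": SyntheticTruth(
        theta=float(np.log(1.28)),
        n_snps=24,
        n_exposure=385_276,
        case_fraction_exposure=80_265 / 385_276,
        n_outcome=173_005,
        case_fraction_outcome=59_851 / 173_005,
    ),
}


def scenario(name: str, **overrides) -> SyntheticTruth:
    """Return a scenario-pack truth, optionally with overridden fields."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    truth = SCENARIOS[name]
    return replace(truth, **overrides) if overrides else truth


def binary_trait_se(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    """Approximate SE of a per-allele log-odds effect estimate."""
    return 1.0 / np.sqrt(2 * maf * (1 - maf) * n * case_fraction * (1 - case_fraction))


def simulate_summary_arrays(truth: SyntheticTruth, rng: np.random.Generator | None = None) -> dict:
    """Core array-level simulation shared by the full generator and by
    replicate studies; returns true and estimated effects plus SEs."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    k = truth.n_snps
    maf = rng.uniform(truth.maf_low, truth.maf_high, size=k)
    # Effect allele coded as the exposure-increasing allele, the usual MR
    # convention; directional pleiotropy is then directional after Egger's
    # orientation step too.
    gamma = rng.uniform(truth.gamma_low, truth.gamma_high, size=k)

    se_x = binary_trait_se(maf, truth.n_exposure, truth.case_fraction_exposure)
    se_y = binary_trait_se(maf, truth.n_outcome, truth.case_fraction_outcome)
    beta_x = gamma + rng.normal(0.0, se_x)

    alpha = np.zeros(k)
    if truth.pleiotropy_mode != "none" and truth.invalid_fraction > 0:
        n_invalid = int(round(truth.invalid_fraction * k))
        idx = rng.choice(k, size=n_invalid, replace=False)
        if truth.pleiotropy_mode == "balanced":
            alpha[idx] = rng.normal(0.0, truth.alpha_sd, size=n_invalid)
        elif truth.pleiotropy_mode == "directional":
            alpha[idx] = rng.normal(truth.alpha_mean, truth.alpha_sd, size=n_invalid)
        else:  # inside_violating: direct effect proportional to instrument strength
            alpha[idx] = truth.alpha_mean * gamma[idx] / np.mean(np.abs(gamma)) + rng.normal(
                0.0, truth.alpha_sd, size=n_invalid
            )
    invalid = alpha != 0

    big_gamma = truth.theta * gamma + alpha
    beta_y = big_gamma + rng.normal(0.0, se_y)
    return {
        "maf": maf,
        "gamma_true": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "big_gamma_true": big_gamma,
        "beta_exposure": beta_x,
        "se_exposure": se_x,
        "beta_outcome": beta_y,
        "se_outcome": se_y,
    }


def generate_two_sample(
    truth: SyntheticTruth,
) -> tuple[list[VariantAssociation], list[VariantAssociation], LDMatrix, SyntheticTruth]:
    """Generate exposure and outcome summary-statistic collections.

    Allele pairs and effect-allele orientation are randomized per study so
    that harmonization is exercised: the outcome table may present a variant
    with swapped alleles (beta negated, eaf complemented), which harmonize()
    must undo. The LD matrix is the identity, with optional correlated
    blocks of size ``ld_block_size`` at r^2 = ``ld_block_r2`` for clumping
    tests. Fully determined by ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    arr = simulate_summary_arrays(truth, rng)
    k = truth.n_snps

    n_pal = int(round(truth.palindromic_fraction * k))
    pal_flags = np.zeros(k, dtype=bool)
    if n_pal:
        pal_flags[rng.choice(k, size=n_pal, replace=False)] = True

    exposure: list[VariantAssociation] = []
    outcome: list[VariantAssociation] = []
    for j in range(k):
        vid = f"rs{1000 + j}"
        chrom = str(1 + j % 22)
        pos = int(1_000_000 * (1 + j))
        pair = _PALINDROMIC_PAIRS[j % 2] if pal_flags[j] else _SAFE_PAIRS[j % len(_SAFE_PAIRS)]
        a1, a2 = pair  # a1 = the allele whose frequency is maf[j]

        for side, beta, se, n, records in (
            ("x", arr["beta_exposure"][j], arr["se_exposure"][j], truth.n_exposure, exposure),
            ("y", arr["beta_outcome"][j], arr["se_outcome"][j], truth.n_outcome, outcome),
        ):
            swap = bool(rng.integers(2))  # present the variant with swapped alleles?
            if swap:
                ea, oa, b, eaf = a2, a1, -beta, 1 - arr["maf"][j]
            else:
                ea, oa, b, eaf = a1, a2, beta, arr["maf"][j]
            p = float(2 * stats.norm.sf(abs(b) / se))
            records.append(
                VariantAssociation(
                    variant_id=vid, effect_allele=ea, other_allele=oa,
                    beta=float(b), se=float(se), pvalue=max(p, 1e-300),
                    eaf=float(eaf), n=n, chrom=chrom, pos=pos,
                )
            )

    ld = _block_ld(k, [v.variant_id for v in exposure], truth.ld_block_size, truth.ld_block_r2)
    return exposure, outcome, ld, truth


def _block_ld(k: int, ids: Sequence[str], block: int, r2: float) -> LDMatrix:
    m = np.eye(k)
    if block > 1:
        for start in range(0, k, block):
            stop = min(start + block, k)
            m[start:stop, start:stop] = r2
            np.fill_diagonal(m[start:stop, start:stop], 1.0)
    return LDMatrix(tuple(ids), m)
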