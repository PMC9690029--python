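"""Prospective power for a two-sample MR analysis with a binary outcome.

The power of an IVW analysis to detect an odds ratio ``OR`` per unit of
exposure depends on the outcome-GWAS sample size ``n``, its case fraction
``K``, the variance of the exposure explained by the instruments ``r2`` and
the significance level ``alpha``:

    power = Phi( |ln OR| * sqrt(n * r2 * K * (1 - K)) - z_{1-alpha/2} )

This is the standard non-centrality approximation for the two-sided Wald
test of the IVW estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerInput", "mr_power_binary"]


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the binary-outcome MR power approximation.

    n: outcome-GWAS sample size; k_ratio: proportion of cases;
    odds_ratio: hypothesized effect per unit of exposure; r2: variance of
    the exposure explained by the instruments; alpha: two-sided level.
    """

    n: int
    k_ratio: float
    odds_ratio: float
    r2: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 < self.k_ratio < 1:
            raise ValueError("case fraction must be in (0, 1)")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def mr_power_binary(inp: PowerInput) -> float:
    """Power in [0, 1] of the two-sided IVW test under the given design.

    Monotone non-decreasing in n, r2, |ln OR| and K(1-K); symmetric under
    OR <-> 1/OR; equals alpha/2 at OR = 1 (the probability mass of one tail).
    """
    b = abs(np.log(inp.odds_ratio))
    z = stats.norm.ppf(1 - inp.alpha / 2)
    ncp = b * np.sqrt(inp.n * inp.r2 * inp.k_ratio * (1 - inp.k_ratio))
    return float(stats.norm.cdf(ncp - z))
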