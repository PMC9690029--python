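"""Instrument selection and strength.

Instruments for a two-sample MR analysis are variants that pass genome-wide
significance for the exposure and are mutually independent after LD
clumping. Instrument strength is summarized by per-variant F-statistics and
by an aggregate F computed from the total variance in the exposure explained
by the instrument set; F well above 10 indicates weak-instrument bias is
negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .summary_data import VariantAssociation

__all__ = [
    "LDMatrix",
    "InstrumentStrength",
    "select_by_pvalue",
    "ld_clump",
    "instrument_strength",
]


@dataclass(frozen=True)
class LDMatrix:
    """Squared-correlation matrix between variants, with unit diagonal."""

    variant_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self):
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        k = len(self.variant_ids)
        if r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {r2.shape}")
        if not np.allclose(r2, r2.T):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")

    def index(self, variant_id: str) -> int | None:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        """Read a square TSV whose header row carries the variant ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=list(self.variant_ids), columns=list(self.variant_ids)).to_csv(path, sep="\t")


@dataclass(frozen=True)
class InstrumentStrength:
    """F-statistics and variance explained for an instrument set.

    ``aggregate_f`` uses (n - k - 1)/k * r2/(1 - r2); ``r2_total`` is the
    standardized-trait approximation sum of 2*eaf*(1-eaf)*beta^2 and is
    ``None`` when any eaf is missing.
    """

    per_snp_f: tuple[float, ...]
    mean_f: float
    r2_total: float | None
    aggregate_f: float | None


def select_by_pvalue(
    assocs: Sequence[VariantAssociation], threshold: float = 5e-8
) -> list[VariantAssociation]:
    """Keep associations with p-value at or below ``threshold``, order preserved."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    selected = [a for a in assocs if a.pvalue <= threshold]
    if not selected:
        warnings.warn("no associations pass the significance threshold", stacklevel=2)
    return selected


def ld_clump(
    assocs: Sequence[VariantAssociation],
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant independent variants.

    Variants are visited by ascending p-value (ties broken by variant_id).
    Each accepted variant eliminates every remaining variant with
    r^2 > ``r2_threshold`` to it; when the LD matrix lacks the pair, the
    pair is instead pruned if both variants lie within ``window_kb`` on the
    same chromosome. A variant with neither an LD entry nor coordinates is a
    hard error.
    """
    for a in assocs:
        in_ld = ld is not None and ld.index(a.variant_id) is not None
        if not in_ld and (a.chrom is None or a.pos is None):
            raise ValueError(
                f"variant {a.variant_id} is absent from the LD matrix and has no coordinates"
            )

    remaining = sorted(assocs, key=lambda a: (a.pvalue, a.variant_id))
    accepted: list[VariantAssociation] = []
    while remaining:
        best = remaining.pop(0)
        accepted.append(best)
        survivors = []
        for cand in remaining:
            if _linked(best, cand, ld, r2_threshold, window_kb):
                continue
            survivors.append(cand)
        remaining = survivors
    return accepted


def _linked(
    a: VariantAssociation,
    b: VariantAssociation,
    ld: LDMatrix | None,
    r2_threshold: float,
    window_kb: float,
) -> bool:
    if ld is not None:
        ia, ib = ld.index(a.variant_id), ld.index(b.variant_id)
        if ia is not None and ib is not None:
            return ld.r2[ia, ib] > r2_threshold
    # No LD entry for the pair: fall back to physical distance.
    if a.chrom is not None and b.chrom is not None and a.chrom == b.chrom:
        if a.pos is not None and b.pos is not None:
            return abs(a.pos - b.pos) <= window_kb * 1000
    return False


def instrument_strength(
    assocs: Sequence[VariantAssociation], n: int
) -> InstrumentStrength:
    """Per-SNP and aggregate instrument strength for the exposure GWAS.

    per-SNP F is (beta/se)^2; the variance explained per SNP uses the
    standardized-trait approximation 2*eaf*(1-eaf)*beta^2.
    """
    k = len(assocs)
    if k == 0:
        raise ValueError("instrument_strength requires at least one association")
    if n <= k + 1:
        raise ValueError(f"sample size n={n} must exceed number of instruments + 1 ({k + 1})")
    per_f = tuple((a.beta / a.se) ** 2 for a in assocs)
    mean_f = float(np.mean(per_f))
    if any(a.eaf is None for a in assocs):
        return InstrumentStrength(per_f, mean_f, None, None)
    r2_total = float(sum(2 * a.eaf * (1 - a.eaf) * a.beta**2 for a in assocs))
    if r2_total >= 1:
        raise ValueError("total variance explained must be < 1; check effect scale")
    aggregate_f = (n - k - 1) / k * r2_total / (1 - r2_total)
    return InstrumentStrength(per_f, mean_f, r2_total, float(aggregate_f))
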