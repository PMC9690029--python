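import numpy as np
import pytest

from bimr.summary_data import HarmonizedInstrument, InstrumentSet, VariantAssociation


def make_instruments(beta_exposure, se_exposure, beta_outcome, se_outcome, ids=None):
    """Build harmonized instruments directly from effect arrays."""
    bx = np.asarray(beta_exposure, dtype=float)
    sx = np.broadcast_to(np.asarray(se_exposure, dtype=float), bx.shape)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.broadcast_to(np.asarray(se_outcome, dtype=float), bx.shape)
    ids = ids or [f"rs{i}" for i in range(len(bx))]
    return [
        HarmonizedInstrument(
            variant_id=ids[j],
            beta_exposure=float(bx[j]), se_exposure=float(sx[j]),
            beta_outcome=float(by[j]), se_outcome=float(sy[j]),
            wald_ratio=float(by[j] / bx[j]), wald_se=float(sy[j] / abs(bx[j])),
            harmonization_action="unchanged",
        )
        for j in range(len(bx))
    ]


def instruments_from_arrays(arr):
    """Harmonized instruments from a simulate_summary_arrays() dict."""
    return make_instruments(
        arr["beta_exposure"], arr["se_exposure"], arr["beta_outcome"], arr["se_outcome"]
    )


def make_set(instruments, exposure="X", outcome="Y"):
    return InstrumentSet(exposure, outcome, list(instruments))


def make_assoc(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-9, eaf=0.3,
               n=100_000, chrom=None, pos=None):
    return VariantAssociation(
        variant_id=vid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=p, eaf=eaf, n=n, chrom=chrom, pos=pos,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20241002)


def random_instrument_set(rng, j=None):
    """A random but well-conditioned instrument set for oracle comparisons."""
    j = j or int(rng.integers(3, 15))
    bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    by = rng.normal(0.3 * bx, 0.02)
    sy = rng.uniform(0.01, 0.05, j)
    return make_instruments(bx, sx, by, sy)
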