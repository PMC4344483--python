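import numpy as np
import pytest

from ascnseg.counts_io import ChromCounts, SampleTotals
from ascnseg.spikein_sim import SimConfig, simulate_pair


def make_counts(xA, xB, yA, yB, chrom="chr1", pos=None) -> ChromCounts:
    """Build a ChromCounts from plain lists."""
    n = len(xA)
    if pos is None:
        pos = np.arange(1, n + 1)
    return ChromCounts(chrom, np.asarray(pos), np.asarray(xA),
                       np.asarray(xB), np.asarray(yA), np.asarray(yB))


def simulate_mixture(T, p_a, p_b, coverage, seed, totals_ratio=1.0):
    """Draw counts directly from the two-component binomial mixture with
    fixed per-allele coverage (the model the EM assumes)."""
    rng = np.random.default_rng(seed)
    n = np.full(T, int(coverage))
    phase = rng.integers(0, 2, T).astype(bool)
    pA = np.where(phase, p_a, p_b)
    pB = np.where(phase, p_b, p_a)
    xA = rng.binomial(n, pA)
    xB = rng.binomial(n, pB)
    return make_counts(xA, xB, n - xA, n - xB)


@pytest.fixture
def equal_totals():
    return SampleTotals(M=1_000_000.0, N=1_000_000.0)


@pytest.fixture
def tiny_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "chrom\tpos\ttumor_ref\ttumor_alt\tnormal_ref\tnormal_alt\n"
        "chr1\t100\t5\t5\t4\t6\n"
        "chr1\t200\t10\t0\t5\t5\n"
    )
    return path


@pytest.fixture
def null_chromosome():
    counts, _ = simulate_pair(SimConfig(T=600, mean_cov=40, seed=42), [])
    return counts
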