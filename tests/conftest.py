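import numpy as np
import pytest

from hiclocal import ContactMatrix
from hiclocal.genome import BinFeatures, GenomeSequence


@pytest.fixture
def toy_genome() -> GenomeSequence:
    """Two tiny chromosomes with hand-placed GATC sites."""
    return GenomeSequence(
        ["chrA", "chrB"],
        {
            "chrA": "AAAGATCTTGGGGATCAA",   # GATC at 3 and 12
            "chrB": "TTTTTTTTTT",           # no sites
        },
    )


@pytest.fixture
def uniform_features():
    """Factory for constant-covariate BinFeatures of a given size."""

    def make(n_bins: int, chrom: str = "chr1", bin_size: int = 2000) -> BinFeatures:
        return BinFeatures(
            chrom, bin_size,
            eff_len=np.full(n_bins, 0.5),
            gc_ends=np.full(n_bins, 0.4),
            end_count=np.full(n_bins, 8),
            mappability=np.ones(n_bins),
        )

    return make


@pytest.fixture
def varying_features():
    """Factory for BinFeatures with seeded, varying covariates (full-rank
    regression design)."""

    def make(n_bins: int, seed: int = 0, chrom: str = "chr1") -> BinFeatures:
        rng = np.random.default_rng(seed)
        return BinFeatures(
            chrom, 2000,
            eff_len=rng.uniform(0.3, 0.9, n_bins),
            gc_ends=rng.uniform(0.3, 0.5, n_bins),
            end_count=rng.integers(4, 14, n_bins).astype(float),
            mappability=np.ones(n_bins),
        )

    return make


@pytest.fixture
def normalized_matrix():
    """Factory for a ContactMatrix already flagged normalized."""

    def make(values: np.ndarray, mask=None, bin_size: int = 2000) -> ContactMatrix:
        n = values.shape[0]
        if mask is None:
            mask = np.ones(n, dtype=bool)
        return ContactMatrix("chrT", bin_size, values, mask, "normalized")

    return make
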