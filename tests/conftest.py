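"""Shared fixtures and small builders for the test suite."""

import numpy as np
import pandas as pd
import pytest

from scvarcal import CountMatrix, NormalizedMatrix


def make_norm(relfreq: pd.DataFrame,
              counts: pd.DataFrame | None = None,
              scale: float = 1e6) -> NormalizedMatrix:
    """Wrap a relative-frequency table as a NormalizedMatrix directly.

    Lets tests control per-gene values exactly without routing through the
    count layer; counts default to the scaled, rounded frequencies (zeros
    preserved)."""
    if counts is None:
        counts = (relfreq * scale).round().astype(int)
    ones = pd.Series(1.0, index=relfreq.columns)
    return NormalizedMatrix(ones, relfreq * scale, relfreq,
                            pd.DataFrame(index=relfreq.columns), counts)


def random_count_matrix(rng, n_genes=10, n_samples=4, density=0.5,
                        high=20) -> CountMatrix:
    counts = rng.integers(1, high, size=(n_genes, n_samples))
    counts[rng.random((n_genes, n_samples)) > density] = 0
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
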