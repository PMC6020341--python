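import warnings

import numpy as np
import pandas as pd
import pytest

from cginoise import noise_stats, synthetic_data

warnings.filterwarnings("ignore", message=".*Identity link.*")


@pytest.fixture(scope="session")
def null_counts():
    """2000 genes x 150 cells with no planted feature effects."""
    counts, truth = synthetic_data.simulate_counts(2000, 150, seed=42)
    return counts, truth


@pytest.fixture(scope="session")
def null_noise_table(null_counts):
    counts, truth = null_counts
    sf = noise_stats.size_factors(counts)
    table = noise_stats.gene_moments(counts, sf)
    fit = noise_stats.fit_mean_cv2(table)
    return noise_stats.residual_cv2(table, fit.a0, fit.a1), fit, truth


@pytest.fixture(scope="session")
def small_annotation():
    """Genes, islands and structure for 300 genes on synthetic chromosomes."""
    counts, truth = synthetic_data.simulate_counts(300, 10, seed=7)
    genes, islands, structure = synthetic_data.simulate_annotations(
        300, seed=7, truth=truth)
    return genes, islands, structure, truth


def standardized(series: pd.Series) -> pd.Series:
    s = series.astype(float)
    return (s - s.mean()) / s.std()
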