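import numpy as np
import pytest

from samgsr import CONTROL, DISEASED, ExpressionStudy


def make_study(values, labels=None, gene_prefix="g", sample_prefix="s"):
    """Small labeled study from a raw matrix (genes x samples)."""
    values = np.asarray(values, dtype=float)
    genes = tuple(f"{gene_prefix}{i + 1}" for i in range(values.shape[0]))
    samples = tuple(f"{sample_prefix}{j + 1}" for j in range(values.shape[1]))
    return ExpressionStudy(genes, samples, values, labels)


def balanced_labels(n_per_class):
    return (CONTROL,) * n_per_class + (DISEASED,) * n_per_class


@pytest.fixture
def rng():
    return np.random.default_rng(20160630)


@pytest.fixture
def small_labeled_study(rng):
    """12 genes x 8 samples of pure noise, 4 vs 4."""
    return make_study(rng.standard_normal((12, 8)), balanced_labels(4))
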