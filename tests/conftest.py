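import numpy as np
import pytest

from grninfer.data_io import Annotation, ExpressionDataset, TFList, concatenate
from grninfer.synthetic import sample_grn, simulate_expression, simulate_knockouts


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_dataset():
    """3 experiments x 3 genes, one single-KO row."""
    values = np.array([[1.0, 2.0, 3.0], [0.5, 1.5, 2.5], [0.1, 2.2, 3.1]])
    annotations = [
        Annotation("wild_type"),
        Annotation("wild_type"),
        Annotation("knockout", frozenset({0})),
    ]
    return ExpressionDataset(values, ["G1", "G2", "G3"], annotations)


@pytest.fixture(scope="session")
def small_grn():
    return sample_grn(20, 30, tf_fraction=0.3, seed=11, noise_sd=0.3)


@pytest.fixture(scope="session")
def bench_grn():
    """The m=50 / 100-edge network used by the stochastic acceptance fixtures."""
    return sample_grn(50, 100, tf_fraction=0.3, seed=0, noise_sd=0.3)


@pytest.fixture(scope="session")
def bench_mf(bench_grn):
    return simulate_expression(bench_grn, 300, "multifactorial", seed=1)


@pytest.fixture(scope="session")
def bench_ko_panel(bench_grn):
    wild_type = simulate_expression(bench_grn, 100, "wild_type", seed=1)
    knockouts = simulate_knockouts(bench_grn, seed=2)
    return concatenate([wild_type, knockouts])


def make_tfs(n_genes, members=None):
    if members is None:
        return TFList.all_genes(n_genes)
    return TFList(frozenset(members), n_genes)
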