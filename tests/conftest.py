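import numpy as np
import pytest

from mdlink import (
    FixtureSpec,
    ModelConfig,
    TrainConfig,
    cross_validate,
    gen_association,
    gen_dag_fixture,
    gen_gene_fixture,
)


@pytest.fixture(scope="session")
def bench_spec() -> FixtureSpec:
    """The planted-block benchmark: 60x20, 4 blocks, p_in=0.5, p_out=0.02."""
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def bench_data(bench_spec):
    adjacency = gen_association(bench_spec)
    gene_net, gene_map = gen_gene_fixture(bench_spec)
    dag = gen_dag_fixture(bench_spec)
    return adjacency, gene_map, gene_net, dag


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """A half-size planted fixture for cheaper training-behavior tests."""
    return FixtureSpec(n_microbes=30, n_diseases=10, n_blocks=2, seed=3)


@pytest.fixture(scope="session")
def small_data(small_spec):
    return gen_association(small_spec)


@pytest.fixture(scope="session")
def bench_cv_report(bench_data):
    """5-fold CV of the full model at the benchmark settings
    (L=2, k=32, 500 epochs); shared across the tests that assert on it."""
    adjacency, gene_map, gene_net, dag = bench_data
    model_config = ModelConfig(embed_dim=32, num_layers=2, seed=1)
    train_config = TrainConfig(epochs=500, seed=1, repeats=1)
    return cross_validate(
        adjacency, model_config, train_config,
        gene_map=gene_map, gene_net=gene_net, dag=dag,
    )
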