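import numpy as np
import pytest

import mrfprio as mp


@pytest.fixture
def universe_abc():
    return mp.GeneUniverse(["A", "B", "C"])


@pytest.fixture
def small_collection():
    """8 genes, two dense-ish ER networks; deterministic."""
    return mp.generate_networks(8, 2, 0.4, seed=1)


@pytest.fixture
def small_params():
    return mp.MRFParams(alpha=0.3, beta=[1.2, 0.8], gamma=[2.0, 1.4])


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small planted-module scenario for evaluation/CLI tests."""
    from mrfprio.synthetic import make_planted_benchmark

    return make_planted_benchmark(
        n_genes=300, K=2, edge_prob=(0.02, 0.03), module_size=20,
        module_edge_prob=0.3, known_fraction=0.5, n_complexes=8,
        complex_size=6, seed=7,
    )


@pytest.fixture
def fast_config():
    return mp.SamplerConfig(burn_in=10, total=50, thin=5,
                            prediction_steps=10, seed=3)


def random_instance(rng, n=10, K=2, p=0.3):
    """Random (collection, labels, params, alpha field) tuple for property tests."""
    coll = mp.generate_networks(n, K, p, seed=int(rng.integers(2**31)))
    labels = rng.integers(0, 2, n).astype(np.int8)
    params = mp.MRFParams(
        alpha=0.0,
        beta=rng.uniform(-3, 3, K),
        gamma=rng.uniform(-3, 3, K),
    )
    alpha_vec = rng.uniform(-3, 3, n)
    return coll, labels, params, alpha_vec
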