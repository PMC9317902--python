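import pytest

import qsarscreen as qs


@pytest.fixture(scope="session")
def small_bench():
    """A small potency benchmark with planted bit-level truth."""
    cfg = qs.SyntheticConfig(n_molecules=120, seed=7, nbits=256)
    return qs.make_benchmark(cfg)


@pytest.fixture(scope="session")
def small_model(small_bench):
    """A trained selected-features model on the small benchmark."""
    ranking = qs.rank_features(small_bench.train, n_trees=60, seed=1)
    curve, model = qs.stepwise_fit(
        small_bench.train, ranking, k_grid=[2, 5, 10, 20, 40], seed=1)
    return curve, model


@pytest.fixture(scope="session")
def small_bbb_model():
    """A trained BBB-permeation (logBB) model on its own synthetic set."""
    cfg = qs.SyntheticConfig(n_molecules=120, seed=11, nbits=256,
                             endpoint_kind="logBB", endpoint="bbb")
    bench = qs.make_benchmark(cfg)
    ranking = qs.rank_features(bench.train, n_trees=60, seed=2)
    _, model = qs.stepwise_fit(bench.train, ranking,
                               k_grid=[2, 5, 10, 20, 40], seed=2)
    return bench, model


@pytest.fixture(scope="session")
def panel():
    return qs.reference_panel()
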