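import numpy as np
import pytest
from hypothesis import settings

import eogkit as ek

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> ek.SimulatorConfig:
    return ek.SimulatorConfig(seed=42)


@pytest.fixture(scope="session")
def clean_config(default_config) -> ek.SimulatorConfig:
    return default_config.noiseless()


@pytest.fixture(scope="session")
def small_bench(default_config) -> ek.EpochSet:
    """30/class noisy benchmark epochs (raw)."""
    return ek.make_benchmark_dataset(30, default_config)


@pytest.fixture(scope="session")
def small_bench_processed(small_bench) -> ek.EpochSet:
    return ek.PreprocessPipeline().process_epochs(small_bench)


@pytest.fixture(scope="session")
def clean_bench_processed(clean_config) -> ek.EpochSet:
    bench = ek.make_benchmark_dataset(10, clean_config)
    return ek.PreprocessPipeline().process_epochs(bench)


@pytest.fixture(scope="session")
def split_small(small_bench_processed):
    return ek.split_train_test(small_bench_processed, 0.75, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
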