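import pytest

from mutstab import synth


@pytest.fixture(scope="session")
def benchmark():
    """Cached access to the synthetic benchmark datasets (expensive to build)."""
    cache = {}

    def get(target: str, task: str, seed: int = 1):
        key = (target, task, seed)
        if key not in cache:
            cache[key] = synth.benchmark_dataset(target, task, seed=seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def planted_binary():
    """Small binary dataset with a strong planted signal."""
    return synth.generate_dataset(
        task="binary", n=320, n_proteins=12, noise_sd=0.25, seed=11
    )


@pytest.fixture(scope="session")
def planted_regression():
    """Small regression dataset with a planted linear target."""
    return synth.generate_dataset(
        task="regression", n=260, n_proteins=10, noise_sd=0.3, seed=7
    )
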