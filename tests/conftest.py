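import warnings

import pytest

from genomealg.fixtures import fixture_model


def _quiet_fixture(kind, n, seed=0, n_genomes=5):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fixture_model(kind, n, seed=seed, n_genomes=n_genomes)


@pytest.fixture(scope="session")
def adjacent5():
    return _quiet_fixture("adjacent-swaps", 5, seed=11)


@pytest.fixture(scope="session")
def adjacent6():
    return _quiet_fixture("adjacent-swaps", 6, seed=13)


@pytest.fixture(scope="session")
def inversions6():
    return _quiet_fixture("small-inversions", 6, seed=17)


@pytest.fixture(scope="session")
def adjacent4():
    return _quiet_fixture("adjacent-swaps", 4, seed=19)
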