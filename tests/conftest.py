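import pytest

from karyoevol import datasets
from karyoevol.chromevol import ModelFamily, RateModelSpec, fit_model
from karyoevol.karyotypes import Sex, select_by_sex
from karyoevol.phylo import grafen_lengths


@pytest.fixture(scope="session")
def fixture_records():
    return datasets.load_karyotypes()


@pytest.fixture(scope="session")
def fixture_records_female(fixture_records):
    return select_by_sex(fixture_records, preference=Sex.female)


@pytest.fixture(scope="session")
def fixture_tree():
    """Packaged topology with Grafen branch lengths (root depth 1)."""
    return grafen_lengths(datasets.load_topology())


@pytest.fixture(scope="session")
def fixture_diploids():
    return datasets.fixture_diploid_numbers()


@pytest.fixture(scope="session")
def fixture_haploids():
    return datasets.fixture_haploid_numbers()


@pytest.fixture(scope="session")
def fixture_best_fit(fixture_tree, fixture_haploids):
    """Constant-rate no-duplication fit on the packaged data.

    Shared across tests: this family is the AIC winner on these data (the
    model-selection test verifies that), and the fit is deterministic
    given the seed.
    """
    spec = RateModelSpec(ModelFamily.CONST_RATE_NO_DUPL, *_bounds(fixture_haploids))
    return fit_model(fixture_tree, fixture_haploids, spec, n_restarts=5, seed=1)


def _bounds(tips):
    from karyoevol.chromevol import default_state_bounds

    return default_state_bounds(tips)
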