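import pytest

from hboc_cea import evaluate_icer, load_parameters


@pytest.fixture(scope="session")
def base_params():
    return load_parameters()


@pytest.fixture(scope="session")
def base_result(base_params):
    """Full base-case incremental analysis, shared across tests."""
    return evaluate_icer(base_params)


@pytest.fixture()
def params(base_params):
    """A mutable copy of the base case for per-test modification."""
    return base_params.copy()
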