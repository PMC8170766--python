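import pytest

from bphcea import default_parameters


@pytest.fixture(scope="session")
def base_params():
    """The base case: 1000 men aged 70, ten annual cycles."""
    return default_parameters()


@pytest.fixture()
def params(base_params):
    """A mutable copy of the base case for per-test modification."""
    return base_params.model_copy(deep=True)
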