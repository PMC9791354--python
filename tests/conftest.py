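import pytest

from landesv import guna_area_tables, guna_coefficients, guna_legend


@pytest.fixture(scope="session")
def legend():
    return guna_legend()


@pytest.fixture(scope="session")
def coeffs(legend):
    return guna_coefficients(legend)


@pytest.fixture(scope="session")
def areas(legend):
    return guna_area_tables(legend)
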