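import pytest

from polbkin import build_scheme, default_rates


@pytest.fixture(scope="session")
def xl_rates():
    return default_rates("crosslinked")


@pytest.fixture(scope="session")
def xl_scheme(xl_rates):
    return build_scheme("crosslinked", xl_rates)


@pytest.fixture(scope="session")
def ux_rates():
    return default_rates("uncrosslinked")


@pytest.fixture(scope="session")
def ux_scheme(ux_rates):
    return build_scheme("uncrosslinked", ux_rates)
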