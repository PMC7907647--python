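import pytest

from hcqpbpk.config import default_drugs
from hcqpbpk.drug import regimen_a
from hcqpbpk.population import healthy_adult


@pytest.fixture(scope="session")
def drugs():
    return default_drugs()


@pytest.fixture(scope="session")
def hcq(drugs):
    return drugs[0]


@pytest.fixture(scope="session")
def dhcq(drugs):
    return drugs[1]


@pytest.fixture(scope="session")
def adult():
    return healthy_adult()


@pytest.fixture(scope="session")
def regimen():
    return regimen_a()


@pytest.fixture(scope="session")
def baseline_result(drugs, adult, regimen):
    """Baseline typical-adult 10-day simulation, shared across tests."""
    from hcqpbpk.engine import build_model, simulate

    model = build_model(drugs, adult, regimen)
    return simulate(model, 240.0)
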