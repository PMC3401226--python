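import pytest

import trapbias as tb


@pytest.fixture(scope="session")
def field_params():
    return tb.PARAMETER_SETS["field"]


@pytest.fixture()
def field_dataset(field_params):
    return tb.simulate_dataset(field_params, 2024)


@pytest.fixture()
def lossy_dataset(field_dataset):
    """Field-data dataset with the heaviest high-catch loss applied."""
    scenario = tb.LossScenario.from_overall_percent("high_catch", 20)
    return tb.apply_loss(field_dataset, scenario, 7)
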