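import matplotlib

matplotlib.use("Agg")

import pytest

from wapfoodweb import Ecopath, build_wap_inputs, make_recovery_scenario


@pytest.fixture(scope="session")
def wap_inputs():
    return build_wap_inputs()


@pytest.fixture(scope="session")
def wap_results(wap_inputs):
    groups, diet, stanzas = wap_inputs
    return Ecopath(groups, diet, stanzas).fit()


@pytest.fixture(scope="session")
def wap_results_zero_ba():
    groups, diet, stanzas = build_wap_inputs(zero_ba=True)
    return Ecopath(groups, diet, stanzas).fit()


@pytest.fixture(scope="session")
def recovery_bundle():
    """Ground-truth synthetic dataset: sigmoid krill driver, steep = 3."""
    return make_recovery_scenario(true_steep=3.0, seed=1)
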