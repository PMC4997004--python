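import warnings

import pytest

from phonemood.synthetic_data import SimConfig, simulate_user


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # small-fixture runs routinely trigger the stratification and
    # skipped-level warnings; they are asserted explicitly where relevant
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*stratification.*", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message=".*level .* skipped.*", category=UserWarning
        )
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(n_users=2, seed=1234)


@pytest.fixture(scope="session")
def sim_user(default_config):
    """One fully simulated user under the default (moderate) conditions."""
    return simulate_user(default_config, "user00")
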