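import numpy as np
import pytest

from hrvalid import (
    build_default_protocol,
    derive_transitions,
    default_device_profiles,
    generate_cohort,
)


@pytest.fixture(scope="session")
def protocol():
    return build_default_protocol()


@pytest.fixture(scope="session")
def transitions(protocol):
    return derive_transitions(protocol)


@pytest.fixture(scope="session")
def profiles():
    return default_device_profiles()


@pytest.fixture(scope="session")
def small_cohort(protocol):
    """Six subjects, three devices spanning the reporting behaviours."""
    keep = {k: v for k, v in default_device_profiles().items()
            if k in ("chest_1s", "wrist_1_3s", "wrist_minute")}
    return generate_cohort(6, keep, seed=11, protocol=protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
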