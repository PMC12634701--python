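import logging

import pytest

from spinerod.geometry import SagittalProfile, build_spine
from spinerod.joints import default_joint_table
from spinerod.rods import default_scenarios
from spinerod.surgery import run_all_scenarios

logging.getLogger("spinerod").setLevel(logging.ERROR)

#: The default study case: severe sagittal imbalance from thoracolumbar
#: kyphosis (PI 60, PT 49, TK 50, LL -12), 60 kg.
DEFAULT_PROFILE = dict(PI=60.0, PT=49.0, TK=50.0, LL=-12.0)


@pytest.fixture(scope="session")
def default_model():
    return build_spine(SagittalProfile(**DEFAULT_PROFILE))


@pytest.fixture(scope="session")
def joint_laws():
    return default_joint_table()


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def protocol_runs(default_model, joint_laws, scenarios):
    """Full staged protocol for all five rod designs (shared: ~30 s)."""
    return run_all_scenarios(default_model, joint_laws, scenarios)
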