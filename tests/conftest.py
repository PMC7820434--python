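import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phytonet.synthetic_data import StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    return generate_study(StudyConfig.small(seed=11))


@pytest.fixture(scope="session")
def default_study():
    return generate_study(StudyConfig.default(seed=11))
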