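import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wearssm.synthetic import default_scenario, generate_participant


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def standard_record():
    """One 14-day participant from the default mid-range scenario."""
    record, truth = generate_participant(default_scenario(seed=1))
    return record, truth


@pytest.fixture(scope="session")
def short_record():
    """A 4-day participant on a 30-min grid (fast multichannel tests)."""
    import dataclasses

    spec = default_scenario(seed=3)
    spec = dataclasses.replace(spec, duration_days=4.0, cgm_step_min=30, aux_step_min=30)
    record, truth = generate_participant(spec)
    return record, truth
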