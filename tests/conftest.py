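import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from irpclean.detector import CaseData  # noqa: E402
from irpclean.simulate import SimConfig, scaled_config, simulate_cohort  # noqa: E402

from oracles import make_separable_case  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten short synthetic cases (~2,000 samples each) for fast tests."""
    cfg = scaled_config(SimConfig(n_cases=10, seed=7), 0.12)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_cases():
    """Trivially separable labeled cases (300 mmHg spikes on 10 mmHg baseline)."""
    rng = np.random.default_rng(99)
    cases = {}
    for i in range(6):
        trace, annot = make_separable_case(f"toy_{i}", 700, rng)
        cases[trace.case_id] = CaseData.from_trace(trace, annot)
    return cases
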