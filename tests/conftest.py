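import numpy as np
import pandas as pd
import pytest

from chromapop.panel import case1_panel, case2_panel
from chromapop.presets import DAY0_OCTANT_PCT, octant_profiles
from chromapop.sample import FlowSample
from chromapop.synthetic import sample_events_from_culture


@pytest.fixture(scope="session")
def panel1():
    return case1_panel()


@pytest.fixture(scope="session")
def panel2():
    return case2_panel()


@pytest.fixture(scope="session")
def day0_fractions():
    total = sum(DAY0_OCTANT_PCT.values())
    return {k: v / total for k, v in DAY0_OCTANT_PCT.items()}


@pytest.fixture(scope="session")
def day0_sample(panel1, day0_fractions):
    """100k-event sample at the measured day-0 octant composition."""
    return sample_events_from_culture(
        day0_fractions, octant_profiles(), panel1, 100_000, seed=20_260_926
    )


@pytest.fixture()
def plain_sample(panel1):
    """Small sample with benign scatter and fixed fluorescence values."""
    n = 8
    ev = pd.DataFrame(
        {
            "FSC-A": np.full(n, 5e5),
            "FSC-H": np.full(n, 5e5),
            "SSC-A": np.full(n, 1.5e5),
            "mCherry": np.full(n, 1.0e4),
            "Venus": np.full(n, 2.0e4),
            "Cerulean": np.full(n, 5.0e3),
        }
    )
    return FlowSample(events=ev)
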