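import numpy as np
import pytest

from vitalfilter.alarm_system import reassess_advisory
from vitalfilter.synthetic import annotate_scenario, example_scenario


@pytest.fixture(scope="session")
def scenario():
    """Canonical fixed-seed annotated scenario shared across the suite."""
    series, truth, limits, off, cfg = example_scenario(seed=1)
    return {"series": series, "truth": truth, "limits": limits,
            "off": off, "config": cfg}


@pytest.fixture(scope="session")
def labelled_events(scenario):
    events = annotate_scenario(
        scenario["series"], scenario["truth"], scenario["limits"],
        off=scenario["off"])
    return reassess_advisory(events)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
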