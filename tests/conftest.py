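import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tsevents as tv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mk_event(event_type, start, length, magnitude, sp=10.0, anchor=None):
    """Shorthand event constructor used across the suite."""
    anchor = start if anchor is None else anchor
    return tv.make_event(event_type, start, start + length, magnitude, anchor, sp)


@pytest.fixture(scope="session")
def eeg_cohort():
    """Standard two-class EEG-like cohort (20 subjects/class, seed 0)."""
    return tv.generate_cohort([tv.eeg_epileptic_spec(), tv.eeg_healthy_spec()], 20, seed=0)


@pytest.fixture(scope="session")
def eeg_cohort_detected(eeg_cohort):
    """Same cohort, re-annotated with detected (not planted) events."""
    return tv.annotate_cohort(eeg_cohort, tv.default_definitions("eeg"))
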