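"""Shared fixtures: the default montage and small synthetic cohorts.

Everything is generated programmatically; the heavier cohort fixtures are
session-scoped so the EEG synthesis cost is paid once per run.
"""

import numpy as np
import pandas as pd
import pytest

from rtmseeg import preprocess as pre, spectral
from rtmseeg.montage import default_montage
from rtmseeg.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_cohort(montage):
    """Tiny 3-arm cohort with fast EEG settings, for structural tests."""
    cfg = CohortConfig(n_per_group=(5, 4, 4), seed=42, sfreq=250.0,
                       n_trains=4, rest_dur=20.0, n_tep_pulses=12)
    return generate_cohort(cfg, montage)


@pytest.fixture(scope="session")
def recovery_cohort(montage):
    """30 Real-group subjects with a planted marker-outcome coupling."""
    cfg = CohortConfig(n_per_group=(30, 2, 2), seed=77, sfreq=250.0,
                       n_trains=8, rest_dur=30.0).with_target_r(0.9)
    return generate_cohort(cfg, montage)


@pytest.fixture(scope="session")
def recovery_marker(recovery_cohort, montage):
    """Measured marker table (first ITI segment, AVR) for the Real group."""
    rows = {}
    for t in recovery_cohort.traits:
        if t.group != "Real":
            continue
        rec = recovery_cohort.treatment_recording(t.subject)
        seg1 = pre.apply_average_reference(
            pre.first_segment(pre.extract_iti_epochs(rec)))
        bp = spectral.epochs_band_power(seg1, (spectral.ALPHA, spectral.LOW_GAMMA))
        rows[t.subject] = bp["LowGamma"] / bp["Alpha"]
    marker = pd.DataFrame(rows).T
    marker.columns = montage.channel_names
    return marker
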