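import numpy as np
import pandas as pd
import pytest

import gaitpheno as gp


@pytest.fixture(scope="session")
def small_cohort():
    """A compact HSP cohort (10 subjects) shared by read-only tests."""
    cfg = gp.CohortConfig(n_subjects=10, seed=42)
    cycles, records, truth = gp.generate_cohort(cfg)
    return cycles, records, truth


@pytest.fixture(scope="session")
def small_healthy():
    return gp.generate_healthy_cohort(n_subjects=8, seed=43)


@pytest.fixture(scope="session")
def small_params(small_cohort):
    cycles, _, _ = small_cohort
    return gp.extract_matrix(cycles)


@pytest.fixture()
def toy_cycle():
    """One fully deterministic cycle with simple analytic channels."""
    t = gp.io.EPOCH_GRID
    channels = {}
    for name in gp.io.SAGITTAL_CHANNELS + gp.io.NON_SAGITTAL_CHANNELS:
        channels[name] = gp.AngleSeries(channel=name, values=np.full(201, 5.0))
    channels["knee_flexion"] = gp.AngleSeries(
        channel="knee_flexion",
        values=30.0 + 25.0 * np.sin(2.0 * np.pi * t / 100.0 - np.pi / 2.0))
    return gp.GaitCycle(
        cycle_id="toy", subject_id="S1", side="left", channels=channels,
        events=gp.GaitEvents(opposite_toe_off=10.0, opposite_initial_contact=50.0,
                             toe_off=60.0),
        stride_time=1.0, stride_length=1.2, subject_height=1.5)
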