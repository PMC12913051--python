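import numpy as np
import pandas as pd
import pytest

from cyclovasc import asl
from cyclovasc.synthetic import CohortTruth, gen_cohort


@pytest.fixture(scope="session")
def schedule():
    """Protocol schedule: 12 PLDs 250-3000 ms, 1500 ms label."""
    return asl.PLDSchedule(plds=tuple(np.arange(0.25, 3.001, 0.25)), tau=1.5,
                           pairs_per_pld=5)


@pytest.fixture(scope="session")
def calibration():
    """M0 calibration whose derived blood M0 is exactly 1000 a.u."""
    unit = asl.M0Calibration(m0_csf=1.0)
    return asl.M0Calibration(m0_csf=1000.0 / unit.m0_blood)


@pytest.fixture(scope="session")
def cohort_tables():
    """One synthetic cohort (panel, outcomes, merged) reused across tests."""
    panel, outcomes = gen_cohort(CohortTruth(seed=42))
    merged = outcomes.merge(panel, on=["participant", "phase"])
    return panel, outcomes, merged
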