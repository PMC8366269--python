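import numpy as np
import pytest

from presbycusis import CohortSimParams, ThresholdGrid, gen_cohort
from presbycusis.abr import STANDARD_FREQUENCIES_KHZ


def make_grid(subject_id="s0", thresholds=None, age_group="juvenile",
              age_days=34.0, ear="left", no_response=None):
    if thresholds is None:
        thresholds = np.full(len(STANDARD_FREQUENCIES_KHZ), 25.0)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim == 0:
        thresholds = np.full(len(STANDARD_FREQUENCIES_KHZ), float(thresholds))
    return ThresholdGrid(subject_id, ear, age_days, age_group,
                         thresholds, no_response)


@pytest.fixture
def juvenile_cohort():
    """Default bifurcated juvenile cohort, n=84, fixed seed."""
    params = CohortSimParams(n_per_group=(84,), ages_days=(34.0,),
                             age_sd_days=(6.0,), seed=20240917)
    return gen_cohort(params)
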