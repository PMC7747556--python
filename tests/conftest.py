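import numpy as np
import pandas as pd
import pytest

from actiflm.io import EpochSeries
from actiflm.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """8 dogs x 7 days (spans a weekend), default effects, fixed seed."""
    return generate_cohort(SimConfig(n_subjects=8, n_days=7, seed=11))


@pytest.fixture(scope="session")
def null_config():
    """Flat covariate structure: no injected effects."""
    return SimConfig(n_subjects=8, n_days=7, seed=12).without_effects()


def make_series(counts, subject_id="dog", start="2020-01-06", missing=None, epoch_minutes=1):
    counts = np.asarray(counts)
    return EpochSeries(
        subject_id=subject_id,
        start=pd.Timestamp(start),
        epoch_minutes=epoch_minutes,
        counts=counts,
        missing=missing,
    )
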