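"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from timeuse24.accelerometry import process_cohort
from timeuse24.coda import close_composition
from timeuse24.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size (29 x 14 d) cohort under the study's default conditions."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def processed_default(default_cohort):
    """(daily summaries, participant time use) of the default cohort."""
    return process_cohort(default_cohort.epochs, default_cohort.diary)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Study conditions with every noise source switched off.

    Targets are the defaults closed to 1440 (non-wear set to zero), so
    the planted compositions are exactly recoverable.
    """
    targets = tuple(np.round(close_composition([484.6, 747.1, 172.4, 17.5]), 1))
    return CohortSpec(
        n_participants=5, n_days=7, target_means=targets,
        between_person_sd=(0.0, 0.0, 0.0, 0.0), nonwear_rate=0.0,
        day_sd=0.0, sleep_efficiency=1.0, diary_error_sd=0.0,
        zero_mvpa_fraction=0.0, dropout_fraction=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return generate_cohort(noiseless_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
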