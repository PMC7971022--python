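"""Shared fixtures: small synthetic cohorts exercised by most tests."""

import datetime as dt
import warnings

import pytest

from wearmob.config import StudyWindow, default_synthetic_config
from wearmob.synthetic import simulate_cohort

warnings.filterwarnings("ignore", message=".*convergence.*", category=UserWarning)


def small_config(seed=0, n=4, n_prior=0, weeks=4, year=2020, **overrides):
    """Default study configuration shrunk to a testable size."""
    cfg = default_synthetic_config(seed=seed)
    start = dt.date(year, 2, 3)
    windows = [StudyWindow(year=year, start=start, end=start + dt.timedelta(days=7 * weeks - 1))]
    if n_prior:
        prev = dt.date(year - 1, 2, 3)
        windows.insert(
            0,
            StudyWindow(year=year - 1, start=prev, end=prev + dt.timedelta(days=7 * weeks - 1)),
        )
    cfg = cfg.model_copy(update={"study_windows": windows, **overrides})
    for s in cfg.sites:
        s.n_participants = n
        s.n_participants_prior_year = n_prior if n_prior else 0
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants/site, 4 weeks of 2020, default dropout and non-wear."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero GPS dropout / zero non-wear: the pipeline-identity regime."""
    cfg = small_config(
        seed=7,
        gps_dropout_prob_indoor=0.0,
        gps_dropout_prob_outdoor=0.0,
        nonwear_day_prob=0.0,
    )
    return simulate_cohort(cfg)
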