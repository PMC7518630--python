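"""Shared fixtures: synthetic cohort and small deterministic series."""

import warnings

import numpy as np
import pandas as pd
import pytest

import actimetrics as am

COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort():
    """40-recording synthetic cohort with graded circadian strength.

    Returns (series_list, ground_truth_table, metrics_table); computed once
    per session because the metric evaluation dominates the suite's runtime.
    """
    series, truth = am.gen_cohort(n_recordings=40, seed=COHORT_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", am.ActimetricsWarning)
        table = am.evaluate_cohort(series, recording_ids=truth["recording_id"])
    return series, truth, table


@pytest.fixture()
def hour_periodic_series():
    """Two whole days whose value is an exact function of the clock hour."""
    rng = np.random.default_rng(3)
    pattern = rng.uniform(0.0, 0.3, 24)
    per_hour = 12  # dt = 300 s
    values = np.tile(np.repeat(pattern, per_hour), 2)
    return am.EnmoSeries(
        start=pd.Timestamp("2021-03-01 00:00:00"), dt=300.0, values=values
    )


@pytest.fixture()
def pure_cosine_series():
    """Seven whole days of a 24-h raised cosine, no noise, dt = 60 s."""
    return am.gen_circadian(
        am.CircadianSpec(
            days=7,
            dt=60.0,
            harmonic_amplitudes=(0.05,),
            noise_sd=0.0,
            baseline=0.1,
        )
    )
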