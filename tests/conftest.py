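import numpy as np
import pytest

from mtcnma import (
    ArmRecord,
    Outcome,
    Treatment,
    TrialRecord,
    TrialSet,
)


def make_trialset(rows, durations=None, covs=None):
    """rows: list of (trial_id, treatment, n, kwargs) tuples."""
    durations = durations or {}
    covs = covs or {}
    arms = [ArmRecord(trial_id=t, treatment=tr, n=n, **kw) for t, tr, n, kw in rows]
    trials = {}
    for t, *_ in rows:
        if t not in trials:
            trials[t] = TrialRecord(
                trial_id=t,
                duration_weeks=durations.get(t, 8.0),
                **covs.get(t, {"mean_age": 10.0, "pct_female": 20.0, "baseline_adhdrs": 38.0}),
            )
    return TrialSet(trials=trials, arms=arms)


@pytest.fixture
def binary_pair_ts():
    """One placebo-controlled trial with CGI-I response counts."""
    return make_trialset(
        [
            ("T1", Treatment.PLACEBO, 100, {"responders": 31}),
            ("T1", Treatment.GXR, 100, {"responders": 59}),
        ]
    )


@pytest.fixture
def continuous_two_trial_ts():
    return make_trialset(
        [
            ("T1", Treatment.PLACEBO, 80, {"mean_change": -8.0, "se_change": 1.2}),
            ("T1", Treatment.GXR, 80, {"mean_change": -16.0, "se_change": 1.2}),
            ("T2", Treatment.PLACEBO, 60, {"mean_change": -9.5, "se_change": 1.5}),
            ("T2", Treatment.ATX, 60, {"mean_change": -15.5, "se_change": 1.5}),
        ]
    )


@pytest.fixture
def three_arm_ts():
    """Placebo / GXR / ATX three-arm trial plus supporting two-arm trials."""
    return make_trialset(
        [
            ("H1", Treatment.PLACEBO, 100, {"mean_change": -15.0, "se_change": 1.3}),
            ("H1", Treatment.GXR, 100, {"mean_change": -23.9, "se_change": 1.25}),
            ("H1", Treatment.ATX, 100, {"mean_change": -18.6, "se_change": 1.2}),
            ("T2", Treatment.PLACEBO, 60, {"mean_change": -9.5, "se_change": 1.5}),
            ("T2", Treatment.ATX, 60, {"mean_change": -15.5, "se_change": 1.5}),
        ]
    )
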