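import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from imukit import arhmm, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 ataxia + 2 control subjects, all tasks/sides, fixed seed."""
    return synthetic.generate_cohort(2, 2, 0, 0.0, seed=11)


def make_three_state_model():
    """Well-separated 3-state AR(1) model: distinct lag-1 signs, unit noise."""
    hyper = arhmm.ARHMMHyperParams(L=3, n_lags=1)
    A = np.zeros((3, 2, 2))
    A[0] = 0.95 * np.eye(2)
    A[1] = -0.95 * np.eye(2)
    Sigma = np.array([np.eye(2)] * 3)
    pi = np.full((3, 3), 0.025)
    np.fill_diagonal(pi, 0.95)
    trans = arhmm.TransitionModel(pi, np.full(3, 1 / 3))
    return arhmm.ARHMMModel(hyper, trans, arhmm.ARDynamics(A, Sigma))


@pytest.fixture(scope="session")
def three_state_data():
    model = make_three_state_model()
    y, states = synthetic.generate_from_arhmm(model, 2000, seed=11)
    return model, y, states


@pytest.fixture(scope="session")
def three_state_stage1(three_state_data):
    model, y, _ = three_state_data
    return arhmm.fit_stage1([y], model.hyper, n_iter=500, burn=100, truncate_at=500, seed=4)


def make_labeled_table(rng, n_subjects=20, n_ataxia=12, repeat=0, feature_maker=None):
    """Minimal labeled feature table for modeling tests.

    ``feature_maker(diagnosis, severity, rng) -> dict`` supplies feature
    columns; names must follow the {task}_{side}_{modality}_... convention
    so they register as TF features.
    """
    rows = []
    for i in range(n_subjects):
        diagnosis = "ataxia" if i < n_ataxia else "control"
        severity = float(rng.uniform(1, 20)) if diagnosis == "ataxia" else 0.0
        n_sessions = 2 if i < repeat else 1
        for v in range(n_sessions):
            row = {
                "subject_id": f"s{i:03d}",
                "session_id": f"s{i:03d}_v{v + 1}",
                "diagnosis": diagnosis,
                "severity": severity,
                "bars_total": severity,
                "bars_right_arm": severity * 4 / 30,
                "bars_arm_leg": severity * 16 / 30,
            }
            row.update(feature_maker(diagnosis, severity, rng))
            rows.append(row)
    return pd.DataFrame(rows)
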