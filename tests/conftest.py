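"""Shared fixtures: tiny hand-checkable panels and seeded simulation designs."""

import numpy as np
import pandas as pd
import pytest

from trajgroup.synthetic_data import GroupTruth, SimulationDesign, simulate_panel


def make_panel(rows, variable="vallecular_pooling"):
    """Build a small long panel from (patient_id, etiology, trial, score) tuples."""
    consistency = {1: "thin", 2: "thin", 3: "thin", 4: "thick", 5: "thick", 6: "thick", 7: "cracker"}
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "etiology": et,
                "trial": t,
                "consistency": consistency.get(t, "thin"),
                "variable": variable,
                "score": s,
            }
            for pid, et, t, s in rows
        ]
    )


def recovery_design(n_subjects=600, seed=0, etiology_effect=0.0, n_trials=7):
    """Three well-separated intercept-only logit groups, mixing 0.5/0.3/0.2.

    Trajectory intercepts -3 / 0 / +3; optional etiology effect on the
    membership logit (zero by default).
    """
    groups = (
        GroupTruth("low", (-3.0, 0.0, 0.0, 0.0)),
        GroupTruth("mid", (0.0, 0.0, 0.0, 0.0)),
        GroupTruth("high", (3.0, 0.0, 0.0, 0.0)),
    )
    e = etiology_effect
    membership = np.array(
        [
            [0.0, 0.0, 0.0],
            [np.log(0.3 / 0.5), e, 0.0],
            [np.log(0.2 / 0.5), 0.0, e],
        ]
    )
    return SimulationDesign(
        n_subjects=n_subjects,
        etiology_probs=(1 / 3, 1 / 3, 1 / 3),
        groups=groups,
        membership_coeffs=membership,
        n_trials=n_trials,
        seed=seed,
    )


def null_design(n_subjects=400, seed=0):
    """Single flat logit group at p = 0.5 (pure Bernoulli noise)."""
    return SimulationDesign(
        n_subjects=n_subjects,
        etiology_probs=(1 / 3, 1 / 3, 1 / 3),
        groups=(GroupTruth("only", (0.0, 0.0, 0.0, 0.0)),),
        membership_coeffs=np.zeros((1, 3)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_panel():
    """One simulated draw from the recovery design, with truth."""
    return simulate_panel(recovery_design(seed=0))


@pytest.fixture
def tiny_panel():
    """Two subjects x two trials, binary scores — small enough to enumerate."""
    return make_panel(
        [
            ("A", "PD", 1, 1),
            ("A", "PD", 2, 0),
            ("B", "HNC", 1, 1),
            ("B", "HNC", 2, 1),
        ]
    )
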