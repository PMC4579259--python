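"""Synthetic FEES-like longitudinal panels from a known trajectory-mixture process.

Every downstream stage (likelihood, selection, posteriors, agreement) is
tested against panels generated here, where the true group memberships and
generating parameters are known.  The generator emulates the structure of a
dysphagia FEES protocol: three etiologies (HNC, PD, DM1), seven swallow
trials in fixed consistency order (1-3 thin liquid, 4-6 thick liquid,
7 bite-sized cracker), latent trajectory groups with flat-extreme and
erratic-intermediate shapes, etiology-dependent group membership, and
incomplete sequences (cracker dropout, truncated thin-liquid runs, fatigue
dropout on the tail).

Generation order: etiology first, then latent group by multinomial logit on
etiology, then scores from the group's trajectory through its link
(Bernoulli for logit; censored-normal draw clamped to the scale bounds and
rounded to the integer scale), and missingness applied last.  Missingness
uses an RNG stream separate from the score stream, so enabling or disabling
it never changes the retained scores at a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from trajgroup.data_model import ETIOLOGIES, validate_panel
from trajgroup.gbtm import MAX_POLY_ORDER, membership_probs, trajectory_mean

DEFAULT_CONSISTENCY_MAP = {1: "thin", 2: "thin", 3: "thin", 4: "thick", 5: "thick", 6: "thick", 7: "cracker"}


@dataclass(frozen=True)
class GroupTruth:
    """True trajectory of one latent group.

    ``poly_coeffs`` are (intercept, linear, quadratic, cubic) on the raw
    trial-index scale; at most cubic.  ``sigma`` is required for the
    censored-normal link only.
    """

    label: str
    poly_coeffs: tuple[float, ...]
    link: str = "logit"
    sigma: float | None = None

    def __post_init__(self):
        if len(self.poly_coeffs) > MAX_POLY_ORDER + 1:
            raise ValueError("poly_coeffs longer than cubic")
        if self.link not in ("logit", "cnorm"):
            raise ValueError(f"unknown link '{self.link}'")
        if self.link == "cnorm" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("censored-normal groups need a positive sigma")


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-pattern probabilities of incomplete swallow sequences (MCAR within pattern).

    ``cracker_dropout``: the final cracker trial is not completed.
    ``thin_truncation``: fewer than three thin-liquid trials (the run stops
    after 1 or 2 thin trials but the rest of the protocol proceeds).
    ``fatigue_dropout``: the sequence ends early at a uniformly chosen trial
    between 4 and 6 (fatigue on the tail).
    """

    cracker_dropout: float = 0.0
    thin_truncation: float = 0.0
    fatigue_dropout: float = 0.0

    def __post_init__(self):
        for name, p in asdict(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass(frozen=True)
class SimulationDesign:
    """Full data-generating process for one synthetic FEES outcome panel."""

    n_subjects: int
    etiology_probs: tuple[float, float, float]  # over (HNC, PD, DM1)
    groups: tuple[GroupTruth, ...]
    membership_coeffs: np.ndarray  # (k, 3): intercept, HNC, DM1 (PD reference)
    n_trials: int = 7
    consistency_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CONSISTENCY_MAP))
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    outcome_variable: str = "vallecular_pooling"
    scale_max: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        probs = np.asarray(self.etiology_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("etiology_probs must be a probability triple over (HNC, PD, DM1)")
        if len(self.groups) == 0:
            raise ValueError("at least one trajectory group required")
        links = {g.link for g in self.groups}
        if len(links) != 1:
            raise ValueError("all groups must share one link")
        coeffs = np.atleast_2d(np.asarray(self.membership_coeffs, dtype=float))
        if coeffs.shape != (len(self.groups), 3):
            raise ValueError(
                f"membership_coeffs must be (k, 3) = ({len(self.groups)}, 3), got {coeffs.shape}"
            )
        if np.any(coeffs[0] != 0.0):
            raise ValueError("the first group is the reference: its membership coefficients must be zero")
        object.__setattr__(self, "membership_coeffs", coeffs)
        missing_trials = [t for t in range(1, self.n_trials + 1) if t not in self.consistency_map]
        if missing_trials:
            raise ValueError(f"consistency_map does not cover trials {missing_trials}")
        if self.scale_max is None:
            object.__setattr__(self, "scale_max", 1 if self.link == "logit" else 4)

    @property
    def link(self) -> str:
        return self.groups[0].link

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated panel."""

    true_group: pd.Series  # subject id -> 0-based group index
    etiology: pd.Series
    design: SimulationDesign

    def to_json(self, path) -> None:
        payload = {
            "true_group": {str(k): int(v) for k, v in self.true_group.items()},
            "etiology": {str(k): str(v) for k, v in self.etiology.items()},
            "design": {
                "n_subjects": self.design.n_subjects,
                "etiology_probs": list(self.design.etiology_probs),
                "n_trials": self.design.n_trials,
                "link": self.design.link,
                "outcome_variable": self.design.outcome_variable,
                "seed": self.design.seed,
                "groups": [
                    {"label": g.label, "poly_coeffs": list(g.poly_coeffs), "sigma": g.sigma}
                    for g in self.design.groups
                ],
                "membership_coeffs": np.asarray(self.design.membership_coeffs).tolist(),
                "missingness": asdict(self.design.missingness),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _etiology_design_vector(etiology: np.ndarray) -> np.ndarray:
    """x_i = [1, 1{HNC}, 1{DM1}] (PD is the reference level)."""
    return np.column_stack(
        [np.ones(len(etiology)), (etiology == "HNC").astype(float), (etiology == "DM1").astype(float)]
    )


def simulate_panel(design: SimulationDesign) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one long panel plus its ground truth from the design.

    Reproducible: the same design (including seed) yields a bit-identical
    panel.  Scores are drawn for the full trial grid first; missingness only
    removes rows afterwards.
    """
    rng_data = np.random.default_rng([design.seed, 11])
    rng_miss = np.random.default_rng([design.seed, 12])
    n, k, T = design.n_subjects, design.k, design.n_trials

    etiology = np.asarray(ETIOLOGIES)[
        rng_data.choice(3, size=n, p=[design.etiology_probs[0], design.etiology_probs[1], design.etiology_probs[2]])
    ]
    # reorder probs: etiology_probs is over (HNC, PD, DM1) = ETIOLOGIES order
    X = _etiology_design_vector(etiology)
    pi = membership_probs(design.membership_coeffs, X)  # (n, k)
    cum = np.cumsum(pi, axis=1)
    group = (rng_data.random((n, 1)) < cum).argmax(axis=1)

    trials = np.arange(1, T + 1, dtype=float)
    eta = np.stack([trajectory_mean(np.asarray(g.poly_coeffs, float), trials) for g in design.groups])
    eta_sub = eta[group]  # (n, T)
    if design.link == "logit":
        scores = (rng_data.random((n, T)) < expit(eta_sub)).astype(float)
    else:
        sigma = np.array([g.sigma for g in design.groups])[group][:, None]
        latent = rng_data.normal(eta_sub, sigma)
        scores = np.clip(np.round(latent), 0, design.scale_max).astype(float)

    keep = np.ones((n, T), dtype=bool)
    ms = design.missingness
    u = rng_miss.random((n, 3))
    stop_at = rng_miss.integers(4, 7, size=n)  # fatigue: last completed trial in 4..6
    n_thin = rng_miss.integers(1, 3, size=n)  # truncation: 1 or 2 thin trials kept
    thin_trials = np.array([t for t in range(1, T + 1) if design.consistency_map[t] == "thin"])
    cracker_trials = np.array([t for t in range(1, T + 1) if design.consistency_map[t] == "cracker"])
    for i in range(n):
        if ms.cracker_dropout and u[i, 0] < ms.cracker_dropout:
            keep[i, cracker_trials - 1] = False
        if ms.thin_truncation and u[i, 1] < ms.thin_truncation and len(thin_trials) > 1:
            keep[i, thin_trials[n_thin[i]:] - 1] = False
        if ms.fatigue_dropout and u[i, 2] < ms.fatigue_dropout:
            keep[i, int(stop_at[i]):] = False  # trials stop_at+1 .. T dropped
        if not keep[i].any():  # never emit an empty subject
            keep[i, 0] = True

    ids = np.array([f"S{i + 1:04d}" for i in range(n)])
    rows = {
        "patient_id": np.repeat(ids, T),
        "etiology": np.repeat(etiology, T),
        "trial": np.tile(np.arange(1, T + 1), n),
        "consistency": np.tile([design.consistency_map[t] for t in range(1, T + 1)], n),
        "variable": design.outcome_variable,
        "score": scores.ravel(),
    }
    panel = pd.DataFrame(rows).loc[keep.ravel()].reset_index(drop=True)
    panel = validate_panel(panel)
    truth = TruthRecord(
        true_group=pd.Series(group, index=ids, name="true_group"),
        etiology=pd.Series(etiology, index=ids, name="etiology"),
        design=design,
    )
    return panel, truth


def default_fees_design(n_subjects: int = 205, seed: int = 0) -> SimulationDesign:
    """The bundled study-like design: 205 subjects, 7 trials, 3 logit groups.

    Groups follow the shapes seen in short swallow protocols: a flat
    low-impairment group, an erratic intermediate group whose cubic bends at
    the thin->thick (trial 3->4) and thick->cracker (trial 6->7) consistency
    transitions, and a flat high-impairment group.  Etiology enters the
    membership logit with effects of plausible clinical magnitude (|log OR|
    up to ~1.2); etiology shares follow the 73/89/43 HNC/PD/DM1 split.
    Missingness rates are illustrative (the protocol's stated causes, not
    calibrated rates).
    """
    groups = (
        GroupTruth("low", (-2.5, 0.0, 0.0, 0.0)),
        GroupTruth("intermediate", (-2.057, 0.802, -0.104, 0.008)),
        GroupTruth("high", (2.2, 0.0, 0.0, 0.0)),
    )
    membership = np.array(
        [
            [0.0, 0.0, 0.0],  # low: reference
            [-0.2, 0.3, -1.2],  # intermediate: DM1 less likely than PD
            [-0.3, 1.2, 0.5],  # high: HNC markedly more likely
        ]
    )
    return SimulationDesign(
        n_subjects=n_subjects,
        etiology_probs=(73 / 205, 89 / 205, 43 / 205),
        groups=groups,
        membership_coeffs=membership,
        n_trials=7,
        missingness=MissingnessSpec(cracker_dropout=0.12, thin_truncation=0.04, fatigue_dropout=0.06),
        outcome_variable="vallecular_pooling",
        seed=seed,
    )


def simulate_rater_pair(
    panel: pd.DataFrame, confusion: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Two independent raters' scores per swallow through an ordinal confusion spec.

    ``confusion[s]`` is the probability vector of the assigned score given
    true score s; both raters draw independently from the same row.  Returns
    one row per panel row with ``rater_a`` and ``rater_b`` columns, the
    fixture for agreement (kappa) testing.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion spec must be a square matrix")
    if np.any(confusion < 0) or not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion spec rows must be probability vectors")
    rng = np.random.default_rng(seed)
    true = panel["score"].to_numpy().astype(int)
    if true.min() < 0 or true.max() >= confusion.shape[0]:
        raise ValueError("panel scores outside the confusion spec's level range")
    cum = np.cumsum(confusion, axis=1)
    a = (rng.random((len(true), 1)) < cum[true]).argmax(axis=1)
    b = (rng.random((len(true), 1)) < cum[true]).argmax(axis=1)
    out = panel[["patient_id", "trial", "variable"]].copy()
    out["true_score"] = true
    out["rater_a"] = a
    out["rater_b"] = b
    return out


def design_with(design: SimulationDesign, **changes) -> SimulationDesign:
    """Functional update helper (dataclasses.replace with validation rerun)."""
    return replace(design, **changes)
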