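"""Posterior classification and etiology-conditioned membership odds ratios.

After fitting, each subject gets a posterior probability (PP) of belonging
to each trajectory group by Bayes' rule,

    PP_ij = pi_j(x_i) P(Y_i | j) / sum_m pi_m(x_i) P(Y_i | m),

computed in log space so that no subject ever underflows to NaN.  Modal
assignment takes the argmax (ties to the lower group label); the average
posterior probability (APP) of a group is the mean PP over its modally
assigned members and is the standard adequacy diagnostic (desirable ~0.7 or
higher).  Mixture proportions are reported as the sample mean of the
model-implied pi (the estimated latent-group sizes), with modal-assignment
shares printed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from trajgroup.gbtm import FittedModel, PanelArrays, _Objective


@dataclass
class PosteriorTable:
    """Per-subject posteriors plus per-group summaries.

    ``subjects``: one row per subject — ``pp_1..pp_k``, ``modal`` (1-based
    group label), ``max_pp``.  ``groups``: one row per group — ``app``,
    ``n_modal``, ``mixture_pct`` (mean model-implied pi, in %),
    ``modal_pct``.
    """

    subjects: pd.DataFrame
    groups: pd.DataFrame
    k: int

    @property
    def pp(self) -> np.ndarray:
        return self.subjects[[f"pp_{j + 1}" for j in range(self.k)]].to_numpy()


def posterior_probs(panel: pd.DataFrame, model: FittedModel) -> PosteriorTable:
    """Posterior group probabilities for every subject in the panel.

    The panel must be the (single-variable, dichotomized-if-logit) panel the
    model was fitted on, or one with the same schema.
    """
    arrays = PanelArrays(panel, model.spec)
    obj = _Objective(arrays, model.spec)
    _, post, pi, _, _ = obj.loglik_parts(model.packed_params())
    k = model.spec.k
    modal = post.argmax(axis=1)  # argmax takes the first max: lower label wins ties

    subjects = pd.DataFrame(
        {"patient_id": arrays.subject_ids},
    )
    if arrays.etiology is not None:
        subjects["etiology"] = arrays.etiology
    for j in range(k):
        subjects[f"pp_{j + 1}"] = post[:, j]
    subjects["modal"] = modal + 1
    subjects["max_pp"] = post.max(axis=1)

    rows = []
    for j in range(k):
        members = modal == j
        rows.append(
            {
                "group": j + 1,
                "n_modal": int(members.sum()),
                "app": float(post[members, j].mean()) if members.any() else np.nan,
                "mixture_pct": 100.0 * float(pi[:, j].mean()),
                "modal_pct": 100.0 * float(members.mean()),
            }
        )
    return PosteriorTable(subjects=subjects, groups=pd.DataFrame(rows), k=k)


def weighted_counts(posterior: PosteriorTable, panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group x etiology table of posterior-weighted member counts.

    For each group j and etiology e: the sum of PP_ij over subjects of
    etiology e whose modal assignment is j — the bar heights of the
    trajectory/etiology charts ("count of subjects assigned to the
    trajectory, weighted by their posterior probabilities").
    """
    sub = posterior.subjects
    if "etiology" not in sub.columns:
        if panel is None:
            raise ValueError("posterior table lacks etiology; pass the source panel")
        et = panel.drop_duplicates("patient_id").set_index("patient_id")["etiology"]
        sub = sub.assign(etiology=sub["patient_id"].map(et).to_numpy())
    pp = posterior.pp
    rows = []
    etiologies = [e for e in ("HNC", "PD", "DM1") if e in set(sub["etiology"])]
    for j in range(posterior.k):
        members = sub["modal"].to_numpy() == j + 1
        for e in etiologies:
            mask = members & (sub["etiology"].to_numpy() == e)
            rows.append({"group": j + 1, "etiology": e, "weighted_count": float(pp[mask, j].sum())})
    return pd.DataFrame(rows).pivot(index="group", columns="etiology", values="weighted_count")[
        etiologies
    ]


@dataclass
class MembershipOR:
    """Odds ratios of trajectory membership per etiology, with 95% Wald CIs.

    One row per (non-reference group, non-reference etiology): the
    multiplicative change in the odds of falling in that trajectory rather
    than the reference trajectory for that etiology relative to the
    reference etiology.  ``ci_available`` is False when the observed
    information was singular (ORs reported without intervals).
    """

    table: pd.DataFrame
    reference_group: int
    reference_etiology: str
    ci_available: bool


def membership_odds_ratios(
    model: FittedModel, reference_group: int = 1, alpha: float = 0.05
) -> MembershipOR:
    """Etiology odds ratios of group membership from the fitted membership logit.

    OR = exp(theta_hat) per etiology-indicator coefficient of each
    non-reference group; CI = exp(theta_hat +/- z_{1-alpha/2} SE) from the
    observed-information covariance.  ``reference_group`` is 1-based; group
    1 (lowest trajectory) is the model's native reference, other choices are
    handled by linear contrast.
    """
    et_cols = [i for i, c in enumerate(model.covariate_names) if c.startswith("etiology[")]
    if not et_cols:
        raise ValueError("model's membership logit does not include etiology")
    k, m = model.spec.k, len(model.covariate_names)
    if not 1 <= reference_group <= k:
        raise ValueError(f"reference_group must be in 1..{k}")
    r = reference_group - 1
    slices = model.param_slices()
    n_par = model.n_params
    z = norm.ppf(1 - alpha / 2)

    rows = []
    ci_ok = model.vcov is not None
    for j in range(k):
        if j == r:
            continue
        for c in et_cols:
            est = model.theta[j, c] - model.theta[r, c]
            # theta[0] is fixed at zero, so the contrast touches only j, r > 0
            contrast = np.zeros(n_par)
            if j > 0:
                contrast[slices[f"theta[{j}]"].start + c] = 1.0
            if r > 0:
                contrast[slices[f"theta[{r}]"].start + c] -= 1.0
            if ci_ok:
                se = float(np.sqrt(contrast @ model.vcov @ contrast))
                lo, hi = np.exp(est - z * se), np.exp(est + z * se)
            else:
                se, lo, hi = np.nan, np.nan, np.nan
            rows.append(
                {
                    "group": j + 1,
                    "etiology": model.covariate_names[c][len("etiology[") : -1],
                    "log_or": float(est),
                    "se": se,
                    "or": float(np.exp(est)),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return MembershipOR(
        table=pd.DataFrame(rows),
        reference_group=reference_group,
        reference_etiology=model.spec.reference_etiology,
        ci_available=ci_ok,
    )
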