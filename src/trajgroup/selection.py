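"""Two-step trajectory-model selection and adequacy checking.

Step 1 fixes all groups at cubic order and scans the group count k from a
maximum (5) down to 1, keeping the model with the smallest
BIC = -2 log L + p log n (ties toward smaller k).  Step 2 keeps k fixed and
prunes polynomial orders: whenever a group's highest-order coefficient is
not significant by a Wald test (|estimate/SE| against the standard normal,
alpha = 0.05), the model is refit with that group's order reduced by one and
the reduction is accepted only if BIC does not increase.  Groups are
processed from the highest current order downward, one term per iteration,
until every retained top term is significant or order 0 is reached.

Adequacy of the final model is judged by the average posterior probability
(APP) of each group against the conventional ~0.7 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from trajgroup.gbtm import FittedModel, TrajectoryModelSpec, fit
from trajgroup.posterior import PosteriorTable


@dataclass
class SelectionTrace:
    """Append-only record of every model tried during selection."""

    records: list[dict] = field(default_factory=list)
    final_spec: TrajectoryModelSpec | None = None
    final_model: FittedModel | None = None
    panel_hash: int | None = None

    def log(self, stage: str, model: FittedModel | None, decision: str, **extra) -> None:
        rec = {"stage": stage, "decision": decision, **extra}
        if model is not None:
            rec.update(
                k=model.spec.k,
                poly_orders=model.spec.poly_orders,
                loglik=model.loglik,
                n_params=model.n_params,
                bic=model.bic,
                converged=model.converged,
            )
        self.records.append(rec)

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


#: BIC differences below this are treated as ties and resolved toward parsimony
BIC_TIE_TOL = 1e-6


def select_k(
    panel: pd.DataFrame,
    link: str,
    max_k: int = 5,
    *,
    bounds: tuple[float, float] = (0.0, 1.0),
    membership_covariates: tuple[str, ...] = (),
    n_starts: int = 3,
    seed: int = 0,
    **spec_kwargs,
) -> SelectionTrace:
    """Step 1: choose the number of groups by BIC under all-cubic trajectories.

    Fits k = max_k down to 1, each group cubic, and selects the smallest
    BIC; ties (within 1e-6) break toward smaller k.  Non-convergent fits are
    recorded and excluded with a warning.
    """
    trace = SelectionTrace()
    candidates: list[FittedModel] = []
    for k in range(max_k, 0, -1):
        spec = TrajectoryModelSpec(
            k=k,
            poly_orders=3,
            link=link,
            bounds=bounds,
            membership_covariates=membership_covariates,
            n_starts=n_starts,
            seed=seed,
            **spec_kwargs,
        )
        try:
            model = fit(panel, spec)
        except Exception as err:  # noqa: BLE001 - selection must survive bad candidates
            warnings.warn(f"k={k} failed to fit: {err}")
            trace.log("select_k", None, f"k={k} failed: {err}", k=k)
            continue
        if not model.converged:
            warnings.warn(f"k={k} did not converge; excluded from selection")
            trace.log("select_k", model, "excluded (non-convergent)")
            continue
        candidates.append(model)
        trace.log("select_k", model, "candidate")
    if not candidates:
        raise RuntimeError("no candidate group count converged")
    # smallest BIC; ties toward smaller k (candidates were fitted at descending k)
    best = candidates[0]
    for model in candidates[1:]:
        if model.bic <= best.bic + BIC_TIE_TOL:
            best = model
    trace.log("select_k", best, f"selected k={best.spec.k}")
    trace.final_spec = best.spec
    trace.final_model = best
    return trace


def wald_pvalues(model: FittedModel) -> dict[int, float]:
    """Two-sided Wald p-value of each group's highest-order trajectory term.

    Computed on the internal (scaled-time) parametrization, where the test
    of the leading coefficient is invariant to the time rescaling.  Groups
    at order 0 are omitted; if the covariance is unavailable the p-value is
    reported as 0.0 (the term is retained).
    """
    out: dict[int, float] = {}
    slices = model.param_slices()
    for j, order in enumerate(model.spec.poly_orders):
        if order == 0:
            continue
        idx = slices[f"beta[{j}]"].stop - 1
        est = model.beta_internal[j][-1]
        if model.vcov is None:
            out[j] = 0.0
            continue
        se = float(np.sqrt(model.vcov[idx, idx]))
        z = est / se if se > 0 else np.inf
        out[j] = float(2.0 * norm.sf(abs(z)))
    return out


def prune_polynomials(
    panel: pd.DataFrame, trace: SelectionTrace, alpha: float = 0.05
) -> SelectionTrace:
    """Step 2: reduce polynomial orders by term significance and BIC.

    Mutates and returns the trace from :func:`select_k`; the final model's
    BIC never exceeds the step-1 winner's.
    """
    if trace.final_model is None:
        raise ValueError("run select_k first")
    current = trace.final_model
    rejected: set[tuple[int, int]] = set()
    while True:
        pvals = wald_pvalues(current)
        orders = current.spec.poly_orders
        # candidate groups with a non-significant top term, highest order first
        cands = [
            j
            for j in sorted(pvals, key=lambda j: (-orders[j], j))
            if pvals[j] > alpha and (j, orders[j]) not in rejected
        ]
        if not cands:
            break
        j = cands[0]
        new_orders = list(orders)
        new_orders[j] = orders[j] - 1
        new_spec = replace(current.spec, poly_orders=tuple(new_orders))
        try:
            candidate = fit(panel, new_spec)
        except Exception as err:  # noqa: BLE001
            warnings.warn(f"pruning refit failed for group {j + 1}: {err}")
            rejected.add((j, orders[j]))
            trace.log("prune", None, f"group {j + 1} refit failed: {err}")
            continue
        if not candidate.converged:
            rejected.add((j, orders[j]))
            trace.log("prune", candidate, f"group {j + 1} reduction rejected (non-convergent)")
            continue
        if candidate.bic <= current.bic + BIC_TIE_TOL:
            trace.log(
                "prune",
                candidate,
                f"group {j + 1} order {orders[j]}->{orders[j] - 1} accepted",
                p_value=pvals[j],
            )
            current = candidate
            rejected.clear()
        else:
            rejected.add((j, orders[j]))
            trace.log(
                "prune",
                candidate,
                f"group {j + 1} order {orders[j]}->{orders[j] - 1} rejected (BIC increase)",
                p_value=pvals[j],
            )
    trace.log("prune", current, "final")
    trace.final_spec = current.spec
    trace.final_model = current
    return trace


@dataclass
class AdequacyReport:
    """Per-group APP against the adequacy threshold."""

    table: pd.DataFrame
    threshold: float
    passed: bool


def check_adequacy(posterior: PosteriorTable, threshold: float = 0.7) -> AdequacyReport:
    """Check each group's average posterior probability against ~0.7.

    Groups with no modal members have undefined APP and are flagged as
    failing (the model claims a class nobody is assigned to).
    """
    tab = posterior.groups.copy()
    tab["app_pass"] = (tab["app"] >= threshold) & tab["app"].notna()
    tab["empty"] = tab["n_modal"] == 0
    passed = bool(tab["app_pass"].all() and not tab["empty"].any())
    return AdequacyReport(table=tab, threshold=threshold, passed=passed)
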