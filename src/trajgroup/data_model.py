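"""Long-format FEES panel representation, outcome registry, dichotomization, CSV I/O.

The universal input is a tidy "long panel": one row per patient x swallow
trial x outcome variable.  Required columns::

    patient_id   opaque subject identifier
    etiology     one of {HNC, PD, DM1}
    trial        integer swallow-trial index, 1-based (1-3 thin liquid,
                 4-6 thick liquid, 7 bite-sized cracker)
    consistency  one of {thin, thick, cracker}
    variable     outcome name (see OUTCOME_REGISTRY)
    score        observed ordinal score

Missing trials are represented by absent rows, never by sentinel scores:
the trajectory likelihood multiplies over observed trials only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

ETIOLOGIES = ("HNC", "PD", "DM1")
#: default reference level for the membership model (largest etiology group)
REFERENCE_ETIOLOGY = "PD"
CONSISTENCIES = ("thin", "thick", "cracker")
PANEL_COLUMNS = ["patient_id", "etiology", "trial", "consistency", "variable", "score"]


class PanelValidationError(ValueError):
    """Raised when a long panel violates the schema, with row-level detail."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Metadata for one FEES outcome variable.

    Parameters
    ----------
    name
        Outcome identifier.
    scale_max
        Top of the ordinal scale (scale minimum is always 0).
    link
        ``"logit"`` for dichotomized three-point variables, ``"cnorm"``
        (censored normal) for the five-point piecemeal-deglutition score
        analyzed as continuous.
    dichotomize_rule
        Mapping original score -> {0, 1}; ``None`` for censored-normal
        outcomes, which pass through unchanged.
    """

    name: str
    scale_max: int
    link: str
    dichotomize_rule: Mapping[int, int] | None = field(default=None)

    @property
    def bounds(self) -> tuple[float, float]:
        return (0.0, float(self.scale_max))


#: The five study outcomes.  Three-point variables are dichotomized to an
#: impaired category "1+" before modeling: pooling/delay variables collapse
#: {1,2} -> 1; penetration-aspiration collapses normal and penetration {0,1}
#: -> 0 so that "1+" means aspiration.  Piecemeal deglutition (0-4) is kept
#: on its original scale under a censored-normal link.
OUTCOME_REGISTRY: dict[str, OutcomeSpec] = {
    "piecemeal_deglutition": OutcomeSpec("piecemeal_deglutition", 4, "cnorm", None),
    "delayed_initiation": OutcomeSpec("delayed_initiation", 2, "logit", {0: 0, 1: 1, 2: 1}),
    "vallecular_pooling": OutcomeSpec("vallecular_pooling", 2, "logit", {0: 0, 1: 1, 2: 1}),
    "pyriform_pooling": OutcomeSpec("pyriform_pooling", 2, "logit", {0: 0, 1: 1, 2: 1}),
    "penetration_aspiration": OutcomeSpec(
        "penetration_aspiration", 2, "logit", {0: 0, 1: 0, 2: 1}
    ),
}


def validate_panel(panel: pd.DataFrame, *, registry: Mapping[str, OutcomeSpec] | None = None) -> pd.DataFrame:
    """Validate a long panel against the schema and the outcome scale bounds.

    Returns the panel (with ``trial`` coerced to int) or raises
    :class:`PanelValidationError` naming the offending rows.
    """
    registry = OUTCOME_REGISTRY if registry is None else registry
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelValidationError(f"panel is missing required columns: {missing}")
    if len(panel) == 0:
        raise PanelValidationError("panel has no rows")

    panel = panel.copy()
    panel["trial"] = pd.to_numeric(panel["trial"], errors="raise").astype(int)
    panel["score"] = pd.to_numeric(panel["score"], errors="raise")

    bad_et = panel.loc[~panel["etiology"].isin(ETIOLOGIES)]
    if len(bad_et):
        raise PanelValidationError(
            f"unknown etiology labels at rows {bad_et.index[:5].tolist()}: "
            f"{sorted(bad_et['etiology'].unique().tolist())}"
        )
    bad_var = panel.loc[~panel["variable"].isin(registry)]
    if len(bad_var):
        raise PanelValidationError(
            f"unknown outcome variables at rows {bad_var.index[:5].tolist()}: "
            f"{sorted(bad_var['variable'].unique().tolist())}"
        )

    dup = panel.duplicated(subset=["patient_id", "trial", "variable"])
    if dup.any():
        raise PanelValidationError(
            f"duplicate (patient_id, trial, variable) keys at rows {panel.index[dup][:5].tolist()}"
        )

    for name, spec in registry.items():
        sub = panel.loc[panel["variable"] == name, "score"]
        if len(sub) == 0:
            continue
        out_of_bounds = (sub < 0) | (sub > spec.scale_max)
        if out_of_bounds.any():
            rows = sub.index[out_of_bounds][:5].tolist()
            raise PanelValidationError(
                f"scores outside [0, {spec.scale_max}] for variable '{name}' at rows {rows}"
            )
        if spec.link == "logit":
            # ordinal three-point variables must carry integer scores
            non_int = sub != sub.round()
            if non_int.any():
                rows = sub.index[non_int][:5].tolist()
                raise PanelValidationError(
                    f"non-integer scores for ordinal variable '{name}' at rows {rows}"
                )
            panel.loc[panel["variable"] == name, "score"] = sub.astype(float).round()
    return panel


def read_panel(path) -> pd.DataFrame:
    """Read and validate a long-panel CSV."""
    return validate_panel(pd.read_csv(path))


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, columns=PANEL_COLUMNS)


def dichotomize(panel: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    """Collapse a three-point ordinal variable to the binary impaired scale.

    Pooling/delay variables map {1, 2} -> "1+" (impaired); penetration-
    aspiration collapses normal and penetration into 0 and keeps aspiration
    as 1.  Censored-normal outcomes (piecemeal deglutition) pass through
    unchanged.  A panel this function has already processed (tracked via
    ``DataFrame.attrs``) is returned unchanged, making the operation
    idempotent — necessary because for penetration-aspiration a dichotomized
    1 (aspiration) would otherwise be re-mapped to 0.  Row count and
    (patient, trial) keys are preserved exactly.
    """
    sub = panel.loc[panel["variable"] == spec.name]
    if len(sub) == 0:
        raise ValueError(f"panel contains no rows for variable '{spec.name}'")
    extra = set(panel["variable"].unique()) - {spec.name}
    if extra:
        raise ValueError(
            f"dichotomize expects a single-variable panel for '{spec.name}'; also found {sorted(extra)}"
        )
    if spec.dichotomize_rule is None or panel.attrs.get("dichotomized"):
        out = panel.copy()
        out.attrs["dichotomized"] = True
        return out
    scores = panel["score"]
    unknown = set(scores.unique()) - set(spec.dichotomize_rule)
    if unknown:
        raise ValueError(
            f"scores {sorted(unknown)} for '{spec.name}' are outside the dichotomization rule"
        )
    out = panel.copy()
    out["score"] = scores.map(spec.dichotomize_rule).astype(float)
    out.attrs["dichotomized"] = True
    return out


def subset_for_variable(
    panel: pd.DataFrame,
    variable: str,
    etiologies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Restrict a panel to one outcome variable and (optionally) an etiology whitelist.

    The study analyzed some variables only on the etiologies whose observer
    agreement was adequate, which shrinks the subject set; this is that
    restriction step.
    """
    if variable not in OUTCOME_REGISTRY:
        raise KeyError(f"unknown outcome variable '{variable}'")
    out = panel.loc[panel["variable"] == variable]
    if etiologies is not None:
        bad = set(etiologies) - set(ETIOLOGIES)
        if bad:
            raise KeyError(f"unknown etiologies in whitelist: {sorted(bad)}")
        out = out.loc[out["etiology"].isin(list(etiologies))]
    if len(out) == 0:
        raise ValueError(
            f"no rows remain for variable '{variable}' with etiologies {etiologies}"
        )
    return out.copy()


def n_subjects(panel: pd.DataFrame) -> int:
    return panel["patient_id"].nunique()
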