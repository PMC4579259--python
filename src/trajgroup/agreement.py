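"""Linear weighted kappa for ordinal FEES scores, with interpretation bands.

Agreement between two raters on an r-level ordinal scale is summarized by
the linear weighted kappa

    kappa_w = 1 - (sum_ij w_ij o_ij) / (sum_ij w_ij e_ij),

with disagreement weights w_ij = |i - j| / (r - 1), observed cell
proportions o and chance-expected proportions e from the marginal products.
For r = 2 this reduces exactly to unweighted Cohen's kappa.  Interpretation
follows the conventional Landis-Koch bands (slight ... almost perfect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix


@dataclass
class AgreementResult:
    kappa: float
    band: str
    n_items: int
    confusion: np.ndarray
    degenerate: bool = False  # both raters constant; kappa set by convention


#: (lower bound inclusive, label); upper bound is the next entry's lower bound.
KAPPA_BANDS = [
    (-np.inf, "less than chance agreement"),
    (0.0, "no agreement beyond chance"),
    (0.01, "slight agreement"),
    (0.21, "fair agreement"),
    (0.41, "moderate agreement"),
    (0.61, "substantial agreement"),
    (0.81, "almost perfect agreement"),
]


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value to its interpretation band.

    Bands are lower-inclusive: [0.61, 0.81) is substantial, [0.81, 1]
    almost perfect; negative values are less than chance.  The printed
    band scheme leaves [0, 0.01) unnamed; it is reported as "no agreement
    beyond chance".
    """
    if kappa > 1.0 + 1e-12:
        raise ValueError(f"kappa cannot exceed 1, got {kappa}")
    label = KAPPA_BANDS[0][1]
    for low, name in KAPPA_BANDS:
        if kappa >= low:
            label = name
    return label


def weighted_kappa(ratings_a, ratings_b, n_levels: int) -> AgreementResult:
    """Linear weighted kappa between two equal-length rating vectors.

    Ratings must lie in 0..n_levels-1.  If both raters are constant and in
    full agreement, chance agreement equals observed agreement and kappa is
    defined as 1 by convention (flagged ``degenerate``).
    """
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("ratings must be two equal-length non-empty vectors")
    if a.min() < 0 or b.min() < 0 or a.max() >= n_levels or b.max() >= n_levels:
        raise ValueError(f"ratings must lie in 0..{n_levels - 1}")
    labels = list(range(n_levels))
    conf = confusion_matrix(a, b, labels=labels)
    if np.array_equal(a, b) and len(np.unique(a)) == 1:
        return AgreementResult(1.0, interpret_kappa(1.0), a.size, conf, degenerate=True)
    kappa = float(cohen_kappa_score(a, b, labels=labels, weights="linear"))
    return AgreementResult(kappa, interpret_kappa(kappa), a.size, conf)


def agreement_screen(
    rater_table: pd.DataFrame, n_levels: int, threshold: float = 0.61
) -> pd.DataFrame:
    """Per-etiology inter-observer agreement screen.

    The study rule: an outcome is analyzed only for etiologies whose
    inter-observer kappa reaches the "substantial" band (>= 0.61 by
    default).  ``rater_table`` needs columns etiology, rater_a, rater_b.
    Returns one row per etiology with kappa, band and the pass flag.
    """
    rows = []
    for etiology, grp in rater_table.groupby("etiology", sort=False):
        res = weighted_kappa(grp["rater_a"], grp["rater_b"], n_levels)
        rows.append(
            {
                "etiology": etiology,
                "kappa": res.kappa,
                "band": res.band,
                "n_items": res.n_items,
                "adequate": res.kappa >= threshold,
            }
        )
    return pd.DataFrame(rows)
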