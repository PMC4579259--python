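"""Observer-agreement screen: simulate two raters and compute weighted kappa.

Scores from the simulated cohort are passed through an ordinal confusion
model (90% diagonal) for two independent raters; agreement is summarized
per etiology with the linear weighted kappa and its interpretation band.
An outcome would enter trajectory modeling only for etiologies reaching at
least substantial agreement (kappa >= 0.61).

Run:  python analysis/02_observer_agreement.py [seed]   (after 01)
"""

import sys
from pathlib import Path

import numpy as np

from trajgroup.agreement import agreement_screen, weighted_kappa
from trajgroup.data_model import read_panel
from trajgroup.synthetic_data import simulate_rater_pair

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
out = Path("results")
panel = read_panel(out / "panel.csv")

diag = 0.90
conf = np.array([[diag, 1 - diag], [1 - diag, diag]])
pair = simulate_rater_pair(panel, conf, seed=seed)
pair["etiology"] = pair["patient_id"].map(
    panel.drop_duplicates("patient_id").set_index("patient_id")["etiology"]
)

overall = weighted_kappa(pair["rater_a"], pair["rater_b"], 2)
print(f"overall inter-observer kappa: {overall.kappa:.3f} ({overall.band}, n={overall.n_items})")

screen = agreement_screen(pair, 2, threshold=0.61)
screen.to_csv(out / "agreement.csv", index=False)
print("\nper-etiology screen (analyze only etiologies with kappa >= 0.61):")
print(screen.round(3).to_string(index=False))
kept = tuple(screen.loc[screen["adequate"], "etiology"])
print(f"\netiologies retained for trajectory modeling: {kept}")
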