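"""Simulate the study-like FEES cohort and describe its structure.

Draws a 205-subject panel from the bundled three-group design (7 swallow
trials: thin, thin, thin, thick, thick, thick, cracker) with
etiology-dependent group membership and protocol-realistic missingness,
then writes the panel, the ground truth, and a descriptive summary.

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

from trajgroup.data_model import write_panel
from trajgroup.synthetic_data import default_fees_design, simulate_panel

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
out = Path("results")
out.mkdir(exist_ok=True)

design = default_fees_design(n_subjects=205, seed=seed)
panel, truth = simulate_panel(design)
write_panel(panel, out / "panel.csv")
truth.to_json(out / "truth.json")

n = panel["patient_id"].nunique()
print(f"simulated cohort: {n} subjects, {len(panel)} observed swallows (seed={seed})")
print("\nsubjects per etiology:")
print(truth.etiology.value_counts().to_string())
print("\ntrue trajectory-group sizes:")
print(truth.true_group.value_counts().sort_index().to_string())

per_subject = panel.groupby("patient_id")["trial"].count()
complete = (per_subject == design.n_trials).mean()
print(f"\ncomplete 7-trial sequences: {100 * complete:.1f}%")
print("observed trials per consistency:")
print(panel["consistency"].value_counts().reindex(["thin", "thick", "cracker"]).to_string())
print(f"\nwrote {out/'panel.csv'} and {out/'truth.json'}")
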