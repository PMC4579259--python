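"""Posterior classification, adequacy, etiology distribution, and odds ratios.

Refits the specification chosen in 03, assigns each subject to the group
with the maximum posterior probability, checks per-group APP against the
0.7 adequacy threshold, tabulates posterior-weighted member counts by
etiology, and reports etiology odds ratios of trajectory membership (group
1 and PD as references).  Also writes the two figures: trajectory curves
and the weighted etiology bar chart.

Run:  python analysis/04_classify_and_odds.py   (after 03)
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from trajgroup.data_model import OUTCOME_REGISTRY, dichotomize, read_panel, subset_for_variable
from trajgroup.gbtm import TrajectoryModelSpec, fit
from trajgroup.posterior import membership_odds_ratios, posterior_probs, weighted_counts
from trajgroup.report import plot_trajectories, plot_weighted_bars
from trajgroup.selection import check_adequacy

out = Path("results")
chosen = json.loads((out / "final_spec.json").read_text())
variable = chosen["variable"]
ospec = OUTCOME_REGISTRY[variable]

panel = dichotomize(subset_for_variable(read_panel(out / "panel.csv"), variable), ospec)
model = fit(
    panel,
    TrajectoryModelSpec(
        k=chosen["k"], poly_orders=tuple(chosen["poly_orders"]), link=ospec.link,
        bounds=ospec.bounds, membership_covariates=("etiology",),
        n_starts=3, seed=chosen["seed"],
    ),
)

post = posterior_probs(panel, model)
post.subjects.to_csv(out / "posterior_subjects.csv", index=False)
post.groups.to_csv(out / "posterior_groups.csv", index=False)

print(f"{variable}: k = {model.spec.k} trajectory groups (1 = low ... {model.spec.k} = high impairment)")
print("\nper-group summary (mixture % = estimated latent-group size):")
print(post.groups.round(3).to_string(index=False))

adequacy = check_adequacy(post, threshold=0.7)
verdict = "adequate" if adequacy.passed else "INADEQUATE"
print(f"\nmodel adequacy (APP >= 0.7 per group): {verdict}")

wc = weighted_counts(post, panel)
wc.to_csv(out / "weighted_counts.csv")
print("\nposterior-weighted member counts by etiology:")
print(wc.round(1).to_string())

ors = membership_odds_ratios(model)
ors.table.to_csv(out / "membership_or.csv", index=False)
print(f"\nmembership odds ratios (reference: trajectory {ors.reference_group}, "
      f"etiology {ors.reference_etiology}):")
print(ors.table[["group", "etiology", "or", "ci_low", "ci_high"]].round(2).to_string(index=False))

fig = plot_trajectories(model, title=variable)
fig.savefig(out / "trajectories.png", dpi=150)
plt.close(fig)
fig = plot_weighted_bars(wc, post, title=variable)
fig.savefig(out / "weighted_bars.png", dpi=150)
plt.close(fig)
print(f"\nfigures written to {out/'trajectories.png'} and {out/'weighted_bars.png'}")
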