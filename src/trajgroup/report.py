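"""End-to-end pipeline driver and figure/table generation.

One invocation analyzes one FEES outcome variable: subset -> dichotomize ->
two-step selection -> posterior classification -> adequacy -> etiology odds
ratios, writing the selection table, parameter table, posterior table, OR
table, two figures (trajectory curves and posterior-weighted etiology bars)
and a machine-readable manifest with the seed and stage checksums.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import trajgroup
from trajgroup.data_model import OUTCOME_REGISTRY, dichotomize, read_panel, subset_for_variable
from trajgroup.gbtm import FittedModel
from trajgroup.posterior import PosteriorTable, membership_odds_ratios, posterior_probs, weighted_counts
from trajgroup.selection import check_adequacy, prune_polynomials, select_k

CONSISTENCY_SPANS = [(1, 3, "thin liquid"), (4, 6, "thick liquid"), (7, 7, "cracker")]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one outcome variable)."""

    panel_path: str
    variable: str
    out_dir: str
    etiologies: tuple[str, ...] | None = None
    max_k: int = 5
    seed: int = 0
    n_starts: int = 3
    membership_covariates: tuple[str, ...] = ("etiology",)
    app_threshold: float = 0.7
    alpha: float = 0.05
    kappa_threshold: float = 0.61


@dataclass
class ReportBundle:
    model: FittedModel
    posterior: PosteriorTable
    adequate: bool
    files: dict[str, str] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis for one outcome variable and write the bundle."""
    if config.variable not in OUTCOME_REGISTRY:
        raise KeyError(f"unknown outcome variable '{config.variable}'")
    spec = OUTCOME_REGISTRY[config.variable]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = read_panel(config.panel_path)
    panel = subset_for_variable(panel, config.variable, config.etiologies)
    panel = dichotomize(panel, spec)

    link = spec.link
    trace = select_k(
        panel,
        link,
        max_k=config.max_k,
        bounds=spec.bounds,
        membership_covariates=config.membership_covariates,
        n_starts=config.n_starts,
        seed=config.seed,
    )
    trace = prune_polynomials(panel, trace, alpha=config.alpha)
    model = trace.final_model

    posterior = posterior_probs(panel, model)
    adequacy = check_adequacy(posterior, threshold=config.app_threshold)
    wc = weighted_counts(posterior, panel)

    files: dict[str, str] = {}

    def save_csv(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, float_format="%.10g", **kw)
        files[name] = str(p)

    save_csv(trace.as_table(), "selection_table.csv", index=False)
    save_csv(model.summary_table(), "parameter_table.csv", index=False)
    save_csv(posterior.subjects, "posterior_subjects.csv", index=False)
    save_csv(posterior.groups, "posterior_groups.csv", index=False)
    save_csv(adequacy.table, "adequacy.csv", index=False)
    save_csv(wc, "weighted_counts.csv")

    if "etiology" in config.membership_covariates and model.spec.k > 1:
        ors = membership_odds_ratios(model)
        save_csv(ors.table, "membership_or.csv", index=False)

    fig = plot_trajectories(model, title=config.variable)
    fig.savefig(out / "trajectories.png", dpi=150)
    plt.close(fig)
    files["trajectories.png"] = str(out / "trajectories.png")
    fig = plot_weighted_bars(wc, posterior, title=config.variable)
    fig.savefig(out / "weighted_bars.png", dpi=150)
    plt.close(fig)
    files["weighted_bars.png"] = str(out / "weighted_bars.png")

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {"trajgroup": trajgroup.__version__, "python": platform.python_version()},
        "final_model": {
            "k": model.spec.k,
            "poly_orders": list(model.spec.poly_orders),
            "link": model.spec.link,
            "loglik": model.loglik,
            "bic": model.bic,
            "converged": model.converged,
        },
        "adequacy": {"passed": adequacy.passed, "threshold": config.app_threshold},
        "checksums": {name: _sha256(Path(p)) for name, p in files.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    files["manifest.json"] = str(out / "manifest.json")

    return ReportBundle(model=model, posterior=posterior, adequate=adequacy.passed, files=files)


def plot_trajectories(model: FittedModel, title: str = "") -> plt.Figure:
    """Fitted group curves over the seven trials with consistency bands.

    Logit link: probability of the impaired ("1+") category.  Censored
    normal: expected score; both stay within their natural ranges.
    """
    trials = np.arange(1, 8)
    fig, ax = plt.subplots(figsize=(6, 4))
    for lo, hi, label in CONSISTENCY_SPANS:
        ax.axvspan(lo - 0.5, hi + 0.5, alpha=0.07, color="gray")
        ax.text((lo + hi) / 2, 1.02, label, transform=ax.get_xaxis_transform(),
                ha="center", fontsize=8, color="dimgray")
    for j in range(model.spec.k):
        curve = model.group_curve(j, trials)
        ax.plot(trials, curve, marker="o", label=f"group {j + 1}")
    ax.set_xlabel("swallow trial")
    if model.spec.link == "logit":
        ax.set_ylabel("P(impaired, 1+)")
        ax.set_ylim(-0.02, 1.02)
    else:
        ax.set_ylabel("expected score")
        ax.set_ylim(model.spec.bounds[0] - 0.1, model.spec.bounds[1] + 0.1)
    ax.set_xticks(trials)
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig


def plot_weighted_bars(
    wc: pd.DataFrame, posterior: PosteriorTable, title: str = ""
) -> plt.Figure:
    """Posterior-weighted member counts per trajectory, split by etiology.

    Bar heights are the weighted counts; each trajectory is annotated with
    its estimated mixture proportion (%).
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = wc.index.to_numpy()
    x = np.arange(len(groups))
    width = 0.8 / max(len(wc.columns), 1)
    for i, et in enumerate(wc.columns):
        ax.bar(x + i * width, wc[et].to_numpy(), width, label=et)
    pct = posterior.groups.set_index("group")["mixture_pct"]
    tops = wc.sum(axis=1).to_numpy()
    for xi, g in zip(x, groups):
        ax.text(xi + 0.4 - width / 2, tops[xi] + 0.5, f"{pct.loc[g]:.1f}%", ha="center", fontsize=8)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([f"traj {g}" for g in groups])
    ax.set_ylabel("posterior-weighted count")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
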