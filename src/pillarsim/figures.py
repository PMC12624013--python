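"""Figure recipes: canned ensemble experiments with CSV + PNG outputs.

Each recipe reruns one of the package's headline ensemble experiments —
growth curves across arrangements with and without energy consumption,
block-parameter sweeps at t = 150, and single-walker motility ensembles —
at a configurable replicate count (the full-scale studies use 100 growth
replicates and 1000 walkers; small ``reps`` values give quick smoke runs).
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .arrangements import ArrangementSpec, ConfigurationError, make_layout
from .io import write_ensemble_csv, write_manifest
from .motility import distribution_mode, motility_correlation, motility_ensemble, records_to_dataframe
from .simulator import SimParams, run_replicates

__all__ = ["RECIPES", "reproduce_figure"]

RECIPES = ("fig4", "fig5C", "fig5E", "fig6A", "fig6B")

_BOX_T = 150  # comparison time step for boxplot summaries


def _growth_condition(layout_spec: ArrangementSpec, energy: bool, reps: int, seed: int, t_max: int):
    layout = make_layout(layout_spec)
    params = SimParams(
        energy_consumption_enabled=energy, t_max=t_max, seed=seed
    )
    return layout, run_replicates(layout, params, reps)


def _fig4(reps: int, seed: int, out: Path) -> dict:
    specs = {
        "fractal": ArrangementSpec("fractal"),
        "array": ArrangementSpec("array"),
        "bulk": ArrangementSpec("bulk"),
    }
    stats_rows = []
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for energy, ax in zip((False, True), axes):
        tag = "energy_on" if energy else "energy_off"
        for name, spec in specs.items():
            layout, ens = _growth_condition(spec, energy, reps, seed, t_max=400)
            write_ensemble_csv(ens, out / f"counts_{name}_{tag}.csv")
            stats = ens.boxplot_stats(_BOX_T)
            stats_rows.append({"arrangement": name, "energy": tag, **stats})
            curve = ens.median_curve()
            ax.plot(curve["t"], curve["median"], label=name)
        ax.set_title(tag.replace("_", " "))
        ax.set_xlabel("t (steps)")
        ax.set_ylabel("bacterial pixel count")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "growth_curves.png", dpi=150)
    plt.close(fig)
    pd.DataFrame(stats_rows).to_csv(out / f"boxstats_t{_BOX_T}.csv", index=False)
    return {"recipe": "fig4", "reps": reps, "t_box": _BOX_T}


def _fig5(vary: str, reps: int, seed: int, out: Path) -> dict:
    if vary == "n":
        conditions = [("n", n, ArrangementSpec("block", block_n=n, intra_block_gap=3))
                      for n in (1, 2, 3, 6, 9)]
    else:
        conditions = [("d", d, ArrangementSpec("block", block_n=3, intra_block_gap=d))
                      for d in (2, 3, 4, 8)]
    conditions.append(("fractal", 0, ArrangementSpec("fractal")))
    rows = []
    labels, data = [], []
    for kind, value, spec in conditions:
        layout, ens = _growth_condition(spec, True, reps, seed, t_max=_BOX_T)
        label = "fractal" if kind == "fractal" else f"{kind}={value}"
        write_ensemble_csv(ens, out / f"counts_{label.replace('=', '')}.csv")
        rows.append({"condition": label, **ens.boxplot_stats(_BOX_T)})
        labels.append(label)
        data.append(ens.counts_at(_BOX_T))
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel(f"bacterial pixel count at t={_BOX_T}")
    fig.tight_layout()
    fig.savefig(out / "boxplot.png", dpi=150)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(out / f"boxstats_t{_BOX_T}.csv", index=False)
    return {"recipe": f"fig5{'C' if vary == 'n' else 'E'}", "reps": reps}


def _fig6(vary: str, runs: int, seed: int, out: Path) -> dict:
    if vary == "n":
        conditions = [(f"n={n}", ArrangementSpec("block", block_n=n, intra_block_gap=3))
                      for n in (1, 2, 3, 6, 9)]
    else:
        conditions = [(f"d={d}", ArrangementSpec("block", block_n=3, intra_block_gap=d))
                      for d in (2, 3, 4, 8)]
    conditions.append(("fractal", ArrangementSpec("fractal")))
    summary = []
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    all_p, all_d, labels = [], [], []
    for label, spec in conditions:
        layout = make_layout(spec)
        records = motility_ensemble(layout, n_runs=runs, horizon=500, seed=seed)
        records_to_dataframe(records).to_csv(
            out / f"motility_{label.replace('=', '')}.csv", index=False
        )
        p = [r.p_outside for r in records]
        d = [r.d_tot for r in records]
        try:
            corr = motility_correlation(records)
        except ConfigurationError:
            corr = float("nan")
        summary.append(
            {
                "condition": label,
                "p_outside_mode": distribution_mode(p),
                "d_tot_median": float(np.median(d)),
                "pearson_r": corr,
                "n_runs": runs,
            }
        )
        all_p.append(p)
        all_d.append(d)
        labels.append(label)
    axes[0].violinplot(all_p, showmedians=True)
    axes[0].set_xticks(range(1, len(labels) + 1), labels, rotation=45)
    axes[0].set_ylabel("p_outside")
    axes[1].violinplot(all_d, showmedians=True)
    axes[1].set_xticks(range(1, len(labels) + 1), labels, rotation=45)
    axes[1].set_ylabel("D_tot")
    fig.tight_layout()
    fig.savefig(out / "violins.png", dpi=150)
    plt.close(fig)
    pd.DataFrame(summary).to_csv(out / "motility_summary.csv", index=False)
    return {"recipe": f"fig6{'A' if vary == 'n' else 'B'}", "runs": runs}


def reproduce_figure(recipe: str, reps: int, seed: int, out: str | Path) -> Path:
    """Run one figure recipe, writing CSVs, a PNG panel, and a manifest.

    ``reps`` is the replicate count (growth recipes) or walker count
    (motility recipes); the full-scale studies use 100 and 1000.
    """
    if recipe not in RECIPES:
        raise ConfigurationError(f"unknown recipe {recipe!r}; valid recipes: {RECIPES}")
    if reps < 1:
        raise ConfigurationError("reps must be ≥ 1")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if recipe == "fig4":
        config = _fig4(reps, seed, out)
    elif recipe == "fig5C":
        config = _fig5("n", reps, seed, out)
    elif recipe == "fig5E":
        config = _fig5("d", reps, seed, out)
    elif recipe == "fig6A":
        config = _fig6("n", reps, seed, out)
    else:
        config = _fig6("d", reps, seed, out)
    config["seed"] = seed
    write_manifest(out, config)
    return out
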