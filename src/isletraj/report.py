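"""Static report generation: figures and tables for a labeled cohort.

Emits (a) waterfall plots of per-participant visits colored by latent
state, split by outcome; (b) the transition-diagram summary table
(entries, exits, transition counts, median entry/exit ages per state)
and a box-style figure; (c) survival curve figures per stratification;
(d) stacked pattern-by-age composition bars.  Output is deterministic
given fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import curves_frame, km_estimate
from .trajectories import PATTERNS, pattern_by_age, pattern_name

CHAIN_COLORS = ("#2ca02c", "#d62728", "#9467bd")


def transition_summary(traj_model, labelings: dict, assignments, cohort) -> pd.DataFrame:
    """Per-state entry/exit/transition counts and median ages."""
    diag = {s.participant_id: s.diagnosed for s in cohort}
    n_states = len(traj_model.state_names)
    rows = []
    entries = {s: [] for s in range(n_states)}
    exits_d = {s: 0 for s in range(n_states)}
    exits_ud = {s: 0 for s in range(n_states)}
    exit_ages = {s: [] for s in range(n_states)}
    trans = np.zeros((n_states, n_states), dtype=int)
    for a in assignments:
        if a.ambiguous:
            continue
        ages, states = labelings[a.participant_id]
        states = np.asarray(states, dtype=int)
        seen = set()
        for age, st in zip(ages, states):
            if st not in seen:
                entries[st].append(float(age))
                seen.add(st)
        for u, v in zip(states[:-1], states[1:]):
            if u != v:
                trans[u, v] += 1
        last = int(states[-1])
        exit_ages[last].append(float(ages[-1]))
        if diag.get(a.participant_id, False):
            exits_d[last] += 1
        else:
            exits_ud[last] += 1
    for st in range(n_states):
        succ = {
            traj_model.name(j): int(trans[st, j])
            for j in range(n_states) if trans[st, j]
        }
        rows.append({
            "state": traj_model.name(st),
            "n_entered": len(entries[st]),
            "median_entry_age": (
                round(float(np.median(entries[st])), 3) if entries[st] else np.nan
            ),
            "n_exit_diagnosed": exits_d[st],
            "n_exit_censored": exits_ud[st],
            "median_exit_age": (
                round(float(np.median(exit_ages[st])), 3) if exit_ages[st] else np.nan
            ),
            "transitions_out": json.dumps(succ, sort_keys=True),
        })
    return pd.DataFrame(rows)


def waterfall_figure(traj_model, labelings: dict, assignments, cohort, path) -> None:
    """Visit dots per participant, colored by state, split by outcome."""
    diag = {s.participant_id: s.diagnosed for s in cohort}
    fig, axes = plt.subplots(1, 2, figsize=(11, 6), sharex=True)
    n_states = len(traj_model.state_names)
    cmap = plt.get_cmap("viridis", n_states)
    for ax, want_dx, title in (
        (axes[0], True, "Diagnosed"), (axes[1], False, "Undiagnosed"),
    ):
        y = 0
        for a in sorted(assignments, key=lambda a: a.participant_id):
            if a.ambiguous or diag.get(a.participant_id) != want_dx:
                continue
            ages, states = labelings[a.participant_id]
            ax.scatter(ages, [y] * len(ages), c=[cmap(s) for s in states], s=4)
            y += 1
        ax.set_title(f"{title} (n={y})" if y else f"{title} (no participants)")
        ax.set_xlabel("age (years)")
    axes[0].set_ylabel("participant")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def transition_figure(traj_model, summary: pd.DataFrame, path) -> None:
    """Box-per-state diagram: box spans median entry to exit age."""
    fig, ax = plt.subplots(figsize=(9, 6))
    y = 0
    for k, chain in enumerate(traj_model.chains):
        for st in chain:
            name = traj_model.name(st)
            row = summary[summary["state"] == name]
            if len(row) == 0 or row["n_entered"].iloc[0] == 0:
                continue
            a0 = row["median_entry_age"].iloc[0]
            a1 = row["median_exit_age"].iloc[0]
            if np.isnan(a0) or np.isnan(a1):
                continue
            ax.barh(
                y, max(a1 - a0, 0.15), left=a0,
                color=CHAIN_COLORS[k % 3], alpha=0.6, height=0.7,
            )
            ax.text(a0, y, f" {name} (n={row['n_entered'].iloc[0]})",
                    va="center", fontsize=8)
            y += 1
    ax.set_xlabel("age (years)")
    ax.set_yticks([])
    ax.set_title("State occupancy spans (median entry to exit age)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def survival_figure(curves: dict, path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    for label in sorted(curves):
        curves[label].plot_survival_function(ax=ax, ci_show=True)
    ax.set_xlabel("years from reference-state entry")
    ax.set_ylabel("diabetes-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pattern_figure(pattern_table: pd.DataFrame, path) -> None:
    pats = [pattern_name(p) for p in PATTERNS]
    fig, axes = plt.subplots(2, 4, figsize=(14, 6), sharey=True)
    for ax, pat in zip(axes.ravel(), pats):
        sub = pattern_table[pattern_table["pattern"] == pat]
        bottom = np.zeros(len(sub))
        for c, color in enumerate(CHAIN_COLORS):
            props = sub[f"prop_tr{c + 1}"].fillna(0).to_numpy()
            ax.bar(sub["age_bin"], props, bottom=bottom, color=color,
                   label=f"TR{c + 1}")
            bottom += props
        ax.set_title(pat, fontsize=9)
        ax.set_xlabel("age bin")
    axes.ravel()[0].set_ylabel("proportion")
    axes.ravel()[0].legend(fontsize=7)
    axes.ravel()[-1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    traj_model, labelings: dict, assignments, cohort,
    stats_results: dict | None, out_dir,
) -> dict:
    """Write all report artifacts into ``out_dir``; returns file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    summary = transition_summary(traj_model, labelings, assignments, cohort)
    summary.to_csv(out / "transition_summary.csv", index=False)
    files["transition_summary"] = "transition_summary.csv"
    transition_figure(traj_model, summary, out / "transition_diagram.png")
    files["transition_diagram"] = "transition_diagram.png"

    waterfall_figure(traj_model, labelings, assignments, cohort,
                     out / "waterfall.png")
    files["waterfall"] = "waterfall.png"

    pattern_table = pattern_by_age(assignments, cohort)
    pattern_table.to_csv(out / "pattern_by_age.csv", index=False)
    pattern_figure(pattern_table, out / "pattern_by_age.png")
    files["pattern_by_age"] = "pattern_by_age.csv"

    if stats_results:
        public = {k: v for k, v in stats_results.items() if not k.startswith("_")}
        with open(out / "stats.json", "w") as fh:
            json.dump(public, fh, indent=1, default=str)
        files["stats"] = "stats.json"
        for name, dataset in stats_results.get("_survival_datasets", {}).items():
            curves = km_estimate(dataset)
            curves_frame(curves).to_csv(out / f"survival_{name}.csv", index=False)
            survival_figure(curves, out / f"survival_{name}.png",
                            f"Diabetes-free survival ({name})")
            files[f"survival_{name}"] = f"survival_{name}.csv"
    return files
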