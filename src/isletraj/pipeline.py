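"""End-to-end analysis orchestration shared by the CLI and scripts."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .stats import anova_tukey, build_survival_dataset, log_rank, survival_at
from .trajectories import (
    assign_participants,
    assignments_frame,
    decompose_trajectories,
    exclusion_counts,
    label_cohort,
    state_entry_ages,
)

log = logging.getLogger("isletraj")


def analyze_cohort(params, cohort, decoding: str = "viterbi") -> dict:
    """Label, decompose, assign, and run the downstream statistics.

    Returns a dict with the trajectory model, labelings, assignments and
    the statistics results (survival datasets under ``_survival_datasets``
    for the report stage).
    """
    labelings = label_cohort(params, cohort, decoding=decoding)
    traj_model = decompose_trajectories(params, labelings)
    assignments = assign_participants(labelings, traj_model, cohort)
    excl = exclusion_counts(assignments)
    log.info("trajectories: %d chains, sizes %s; %d/%d ambiguous",
             len(traj_model.chains),
             [len(c) for c in traj_model.chains],
             excl["n_ambiguous"], excl["n_total"])

    results: dict = {"exclusions": excl,
                     "chain_sizes": [len(c) for c in traj_model.chains]}
    diag = {s.participant_id: s.diagnosed for s in cohort}

    # seroconversion-age ANOVA per outcome group
    for outcome in (True, False):
        groups: dict = {}
        for a in assignments:
            if a.ambiguous or a.seroconversion_age is None:
                continue
            if diag.get(a.participant_id, False) != outcome:
                continue
            groups.setdefault(f"TR{a.chain + 1}", []).append(a.seroconversion_age)
        key = "seroconversion_anova_" + ("diagnosed" if outcome else "undiagnosed")
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            res, pairwise = anova_tukey(groups)
            results[key] = res.to_dict()
            results[key]["tukey"] = pairwise.to_dict(orient="records")

    # survival from first antibody-positive state, several stratifications
    datasets = {}
    for name, split in (
        ("trajectory", None),
        ("sex", "sex"),
        ("hla", "hla"),
        ("median_entry_age", "median_entry_age"),
    ):
        ds = build_survival_dataset(
            assignments, labelings, cohort, traj_model,
            reference="first_positive", split=split,
        )
        if len(ds.time) and len(ds.strata()) >= 2:
            datasets[name] = ds
    ds = build_survival_dataset(
        assignments, labelings, cohort, traj_model,
        reference="gada_ia2a", split="reference_state",
    )
    if len(ds.time) and len(ds.strata()) >= 2:
        datasets["gada_ia2a_states"] = ds

    from .stats import km_estimate

    for name, ds in datasets.items():
        overall, pairwise = log_rank(ds)
        entry = {"overall": overall.to_dict(),
                 "pairwise": pairwise.to_dict(orient="records"),
                 "n_excluded_no_reference": ds.n_excluded}
        if name == "trajectory":
            curves = km_estimate(ds)
            entry["survival_at_5y"] = {
                str(k): survival_at(curves[k], 5.0) for k in curves
            }
        results[f"logrank_{name}"] = entry
    results["_survival_datasets"] = datasets

    return {
        "traj_model": traj_model,
        "labelings": labelings,
        "assignments": assignments,
        "entry_ages": state_entry_ages(assignments, labelings, cohort,
                                       n_states=params.n_states),
        "stats": results,
    }


def write_manifest(out_dir, seed, config: dict | None = None,
                   inputs: dict | None = None) -> Path:
    """Record seed, software version, config hash and input checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "inputs": {
            str(k): hashlib.sha256(Path(v).read_bytes()).hexdigest()
            for k, v in (inputs or {}).items() if Path(v).exists()
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def assignments_to_csv(result: dict, path) -> None:
    assignments_frame(result["assignments"], result["traj_model"]).to_csv(
        path, index=False
    )
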