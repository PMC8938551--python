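"""Cohort file formats and inclusion filters.

Two CSV files describe a cohort:

``visits.csv``
    participant_id, age_years, gada, iaa, ia2a (each 0/1/NA)
``participants.csv``
    participant_id, sex (M/F), hla_dr, diagnosed (0/1),
    diagnosis_age_years (NA when undiagnosed), last_obs_age_years

Round-trips are lossless; unknown columns are preserved on the frames
returned by :func:`read_cohort_frames`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import HLA_LEVELS, MISSING, SEX_LEVELS, ParticipantSeries

VISIT_COLUMNS = ["participant_id", "age_years", "gada", "iaa", "ia2a"]
PARTICIPANT_COLUMNS = [
    "participant_id", "sex", "hla_dr", "diagnosed",
    "diagnosis_age_years", "last_obs_age_years",
]


class SchemaError(ValueError):
    pass


def cohort_to_frames(cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a cohort to (visits, participants) frames."""
    vrows, prows = [], []
    for s in cohort:
        for age, o in zip(s.ages, s.obs):
            vrows.append({
                "participant_id": s.participant_id,
                "age_years": round(float(age), 3),
                "gada": _enc(o[0]), "iaa": _enc(o[1]), "ia2a": _enc(o[2]),
            })
        prows.append({
            "participant_id": s.participant_id,
            "sex": s.sex,
            "hla_dr": s.hla_dr,
            "diagnosed": int(s.diagnosed),
            "diagnosis_age_years": (
                round(float(s.diagnosis_age), 3) if s.diagnosed else np.nan
            ),
            "last_obs_age_years": round(float(s.last_obs_age), 3),
        })
    return (
        pd.DataFrame(vrows, columns=VISIT_COLUMNS),
        pd.DataFrame(prows, columns=PARTICIPANT_COLUMNS),
    )


def _enc(v) -> float:
    return np.nan if v == MISSING else int(v)


def frames_to_cohort(
    visits: pd.DataFrame, participants: pd.DataFrame
) -> list[ParticipantSeries]:
    """Build a cohort from (visits, participants) frames, with validation."""
    _check_columns(visits, VISIT_COLUMNS, "visits")
    _check_columns(participants, PARTICIPANT_COLUMNS, "participants")
    known = set(participants["participant_id"])
    unknown = visits.loc[~visits["participant_id"].isin(known)]
    if len(unknown):
        row = unknown.index[0]
        raise SchemaError(
            f"visits row {row}: unknown participant "
            f"{unknown['participant_id'].iloc[0]!r}"
        )
    dup = visits.duplicated(subset=["participant_id", "age_years"])
    if dup.any():
        row = visits.index[dup][0]
        raise SchemaError(
            f"visits row {row}: duplicate (participant, age) entry; merge "
            f"duplicate ages explicitly before writing"
        )
    cohort = []
    grouped = dict(list(visits.groupby("participant_id", sort=False)))
    for _, p in participants.iterrows():
        pid = p["participant_id"]
        if pid not in grouped:
            raise SchemaError(f"participant {pid!r} has no visits")
        g = grouped[pid].sort_values("age_years")
        obs = np.full((len(g), 3), MISSING, dtype=np.int8)
        for j, col in enumerate(("gada", "iaa", "ia2a")):
            vals = g[col].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if np.any(~np.isin(vals[ok], (0, 1))):
                bad = g.index[ok][~np.isin(vals[ok], (0, 1))][0]
                raise SchemaError(f"visits row {bad}: {col} must be 0/1/NA")
            obs[ok, j] = vals[ok].astype(np.int8)
        sex = str(p["sex"])
        if sex not in SEX_LEVELS:
            raise SchemaError(f"participant {pid!r}: sex must be M or F")
        hla = str(p["hla_dr"])
        if hla not in HLA_LEVELS:
            raise SchemaError(f"participant {pid!r}: unknown hla_dr {hla!r}")
        diagnosed = bool(int(p["diagnosed"]))
        dx = p["diagnosis_age_years"]
        dx = None if pd.isna(dx) else float(dx)
        if diagnosed and dx is None:
            raise SchemaError(
                f"participant {pid!r}: diagnosed without diagnosis age"
            )
        if not diagnosed:
            dx = None
        cohort.append(ParticipantSeries(
            participant_id=str(pid),
            ages=g["age_years"].to_numpy(dtype=float),
            obs=obs,
            diagnosed=diagnosed,
            diagnosis_age=dx,
            last_obs_age=float(p["last_obs_age_years"]),
            sex=sex,
            hla_dr=hla,
        ))
    return cohort


def _check_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def write_cohort(cohort, visits_path, participants_path) -> None:
    visits, participants = cohort_to_frames(cohort)
    visits.to_csv(visits_path, index=False)
    participants.to_csv(participants_path, index=False)


def read_cohort(visits_path, participants_path) -> list[ParticipantSeries]:
    visits = pd.read_csv(Path(visits_path))
    participants = pd.read_csv(Path(participants_path))
    return frames_to_cohort(visits, participants)


def cohort_filter(cohort, mode: str = "analysis") -> tuple[list, dict]:
    """Apply the cohort inclusion rules; returns (kept, exclusion report).

    ``analysis`` keeps participants with at least one measurement at or
    before age 2.5 years, at least one positive measurement ever, and at
    least 2 visits.  ``training`` additionally requires a diagnosis
    within 15 years of follow-up and at least 3 visits.
    """
    if mode not in ("analysis", "training"):
        raise ValueError(f"unknown filter mode {mode!r}")
    report = {
        "mode": mode,
        "n_input": len(cohort),
        "no_early_measurement": 0,
        "never_positive": 0,
        "too_few_visits": 0,
        "not_diagnosed": 0,
        "n_kept": 0,
    }
    min_visits = 3 if mode == "training" else 2
    kept = []
    for s in cohort:
        measured = (s.obs != MISSING).any(axis=1)
        if not np.any(measured & (s.ages <= 2.5)):
            report["no_early_measurement"] += 1
            continue
        if not s.ever_positive():
            report["never_positive"] += 1
            continue
        if s.n_visits < min_visits:
            report["too_few_visits"] += 1
            continue
        if mode == "training" and not (
            s.diagnosed and s.diagnosis_age is not None and s.diagnosis_age <= 15.0
        ):
            report["not_diagnosed"] += 1
            continue
        kept.append(s)
    report["n_kept"] = len(kept)
    return kept, report
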