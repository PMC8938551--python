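"""Participant-level longitudinal data containers.

A cohort is a list of :class:`ParticipantSeries`, each holding one
participant's ordered visits.  At every visit the presence or absence of
three islet autoantibodies (GADA, IAA, IA-2A) is recorded; a measurement
may be missing.  Observations are encoded as ``int8``: ``1`` positive,
``0`` negative, ``-1`` missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

ANTIBODIES = ("gada", "iaa", "ia2a")
N_ANTIBODIES = 3

MISSING = -1
NEGATIVE = 0
POSITIVE = 1

SEX_LEVELS = ("M", "F")
HLA_LEVELS = ("DR3/4", "DR4/X", "DR3/X", "DRX/X", "Unknown")


@dataclass
class ParticipantSeries:
    """One participant's ordered visit history with outcome and covariates.

    Parameters
    ----------
    participant_id : str
        Unique identifier.
    ages : (T,) float array
        Visit ages in decimal years, strictly increasing, all >= 0.
    obs : (T, 3) int8 array
        Antibody observations (GADA, IAA, IA-2A); 1/0/-1 for
        positive/negative/missing.
    diagnosed : bool
        Whether type 1 diabetes was diagnosed during follow-up.
    diagnosis_age : float or None
        Age at diagnosis; present iff ``diagnosed``.
    last_obs_age : float
        Age at end of observation (>= final visit age).
    sex : {"M", "F"}
    hla_dr : str
        HLA-DR risk category, one of ``HLA_LEVELS``.
    """

    participant_id: str
    ages: np.ndarray
    obs: np.ndarray
    diagnosed: bool = False
    diagnosis_age: float | None = None
    last_obs_age: float | None = None
    sex: str = "M"
    hla_dr: str = "Unknown"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.obs = np.asarray(self.obs, dtype=np.int8)
        if self.ages.ndim != 1 or len(self.ages) == 0:
            raise ValueError("ages must be a nonempty 1-d array")
        if self.obs.shape != (len(self.ages), N_ANTIBODIES):
            raise ValueError(
                f"obs shape {self.obs.shape} does not match "
                f"({len(self.ages)}, {N_ANTIBODIES})"
            )
        if np.any(self.ages < 0):
            raise ValueError("visit ages must be >= 0")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(
                f"visit ages must be strictly increasing for participant "
                f"{self.participant_id!r}"
            )
        if not np.isin(self.obs, (MISSING, NEGATIVE, POSITIVE)).all():
            raise ValueError("observations must be coded 1/0/-1")
        if self.diagnosed and self.diagnosis_age is None:
            raise ValueError("diagnosis_age required when diagnosed")
        if not self.diagnosed and self.diagnosis_age is not None:
            raise ValueError("diagnosis_age present but diagnosed is False")
        if self.last_obs_age is None:
            self.last_obs_age = float(self.ages[-1])
        if self.last_obs_age < self.ages[-1] - 1e-9:
            raise ValueError("last_obs_age precedes final visit age")

    @property
    def n_visits(self) -> int:
        return len(self.ages)

    @property
    def outcome_age(self) -> float:
        """Diagnosis age if diagnosed, else censoring (last observation) age."""
        return float(self.diagnosis_age) if self.diagnosed else float(self.last_obs_age)

    def ever_positive(self) -> bool:
        return bool((self.obs == POSITIVE).any())

    def merge_duplicate_ages(self) -> "ParticipantSeries":
        """Merge visits recorded at identical ages.

        Observations are combined per antibody; a missing value defers to a
        recorded one, and conflicting recorded values raise ``ValueError``.
        """
        ages, inv = np.unique(np.round(self.ages, 9), return_inverse=True)
        if len(ages) == len(self.ages):
            return self
        obs = np.full((len(ages), N_ANTIBODIES), MISSING, dtype=np.int8)
        for k, a in enumerate(inv):
            for j in range(N_ANTIBODIES):
                v = self.obs[k, j]
                if v == MISSING:
                    continue
                if obs[a, j] == MISSING:
                    obs[a, j] = v
                elif obs[a, j] != v:
                    raise ValueError(
                        f"conflicting observations at age {ages[a]} for "
                        f"participant {self.participant_id!r}"
                    )
        return replace(self, ages=ages, obs=obs)


@dataclass
class PackedCohort:
    """Padded array view of a cohort, used by the CT-HMM internals.

    Fields
    ------
    ages : (N, T) float, padded with the last valid age
    obs : (N, T, 3) int8, padded visits all-missing
    mask : (N, T) bool, True at real visits
    dt : (N, T-1) float, inter-visit gaps (0 at padding)
    n_visits : (N,) int
    ids : list of participant ids in row order
    """

    ages: np.ndarray
    obs: np.ndarray
    mask: np.ndarray
    dt: np.ndarray
    n_visits: np.ndarray
    ids: list = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return self.ages.shape[0]

    @property
    def total_visits(self) -> int:
        return int(self.n_visits.sum())


def pack_cohort(cohort: Sequence[ParticipantSeries]) -> PackedCohort:
    """Stack a cohort into padded arrays (one row per participant)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)
    t_max = max(s.n_visits for s in cohort)
    ages = np.zeros((n, t_max))
    obs = np.full((n, t_max, N_ANTIBODIES), MISSING, dtype=np.int8)
    mask = np.zeros((n, t_max), dtype=bool)
    n_visits = np.zeros(n, dtype=int)
    for i, s in enumerate(cohort):
        t = s.n_visits
        ages[i, :t] = s.ages
        ages[i, t:] = s.ages[-1]
        obs[i, :t] = s.obs
        mask[i, :t] = True
        n_visits[i] = t
    dt = np.diff(ages, axis=1)
    return PackedCohort(
        ages=ages, obs=obs, mask=mask, dt=dt, n_visits=n_visits,
        ids=[s.participant_id for s in cohort],
    )
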