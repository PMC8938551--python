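"""Trajectory semantics on top of a fitted model and labeled visits.

A fitted rate matrix is pruned at a small rate threshold and split into
weakly connected components ("chains"); each chain is ordered along its
thresholded edges, its start is the state with the lowest total antibody
positivity, and chains are named TR1/TR2/TR3 by how strongly the state
after the start is multiple-antibody positive (multiple-first, then
IAA-first, then GADA-first on model fits shaped like the published one).
Participants whose labeled path stays inside one chain are assigned to
it; paths spanning chains are flagged ambiguous and excluded from the
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ANTIBODIES, MISSING, POSITIVE, ParticipantSeries
from .cthmm import CTHMMParams

GADA, IAA, IA2A = 0, 1, 2


@dataclass
class TrajectoryModel:
    """Partition of latent states into ordered disjoint chains."""

    chains: list                      # list of ordered state-index lists
    state_names: dict                 # state index -> "TR{k}-{j}"
    emissions: np.ndarray
    degenerate: bool = False
    state_summaries: pd.DataFrame | None = None

    @property
    def start_states(self) -> list:
        return [c[0] for c in self.chains]

    @property
    def first_positive_states(self) -> list:
        """The state right after each chain start (TR1-1, TR2-1, TR3-1)."""
        return [c[1] if len(c) > 1 else c[0] for c in self.chains]

    def chain_of(self, state: int) -> int | None:
        for k, c in enumerate(self.chains):
            if state in c:
                return k
        return None

    def name(self, state: int) -> str:
        return self.state_names.get(state, f"S{state}")


@dataclass
class ParticipantAssignment:
    participant_id: str
    chain: int | None                 # None when ambiguous
    states: np.ndarray
    first_positive_entry_age: float | None = None
    seroconversion_age: float | None = None

    @property
    def ambiguous(self) -> bool:
        return self.chain is None


def _multiple_positive_prob(row: np.ndarray) -> float:
    """P(at least 2 of 3 antibodies positive) under independent Bernoullis."""
    g, i, a = row
    return (
        g * i * (1 - a) + g * a * (1 - i) + i * a * (1 - g) + g * i * a
    )


def decompose_trajectories(
    params: CTHMMParams,
    labelings: dict | None = None,
    rate_threshold: float | None = None,
) -> TrajectoryModel:
    """Split the fitted states into ordered disjoint chains.

    Parameters
    ----------
    params : fitted model.
    labelings : optional dict participant_id -> (ages, state path);
        used to break ordering ties by median entry age.
    rate_threshold : rates at or below this are pruned; defaults to 1% of
        the largest off-diagonal rate.
    """
    q = params.rate_matrix
    s = params.n_states
    off = q - np.diag(np.diag(q))
    max_rate = off.max()
    if rate_threshold is None:
        rate_threshold = 0.01 * max_rate
    g = nx.DiGraph()
    g.add_nodes_from(range(s))
    for i in range(s):
        for j in range(s):
            if i != j and off[i, j] > rate_threshold:
                g.add_edge(i, j, rate=off[i, j])
    degenerate = g.number_of_edges() == 0

    entry_age = _median_entry_ages(labelings, s) if labelings else np.full(s, np.nan)

    chains = []
    for comp in nx.weakly_connected_components(g):
        sub = g.subgraph(comp)
        try:
            order = list(
                nx.lexicographical_topological_sort(
                    sub,
                    key=lambda v: (
                        entry_age[v] if np.isfinite(entry_age[v]) else float(v)
                    ),
                )
            )
        except nx.NetworkXUnfeasible:
            # cyclic thresholded graph: fall back to entry-age ordering
            order = sorted(
                comp,
                key=lambda v: (
                    entry_age[v] if np.isfinite(entry_age[v]) else float(v)
                ),
            )
        # chain start = least antibody-positive state in the component
        start = min(order, key=lambda v: params.emissions[v].sum())
        order.remove(start)
        chains.append([start] + order)

    # name chains by how multiple-antibody-positive the post-start state is
    def chain_key(chain):
        nxt = chain[1] if len(chain) > 1 else chain[0]
        return -_multiple_positive_prob(params.emissions[nxt])

    chains.sort(key=chain_key)
    names = {
        st: f"TR{k + 1}-{j}"
        for k, chain in enumerate(chains)
        for j, st in enumerate(chain)
    }
    return TrajectoryModel(
        chains=chains,
        state_names=names,
        emissions=params.emissions,
        degenerate=degenerate,
    )


def _median_entry_ages(labelings: dict, n_states: int) -> np.ndarray:
    entries: list[list[float]] = [[] for _ in range(n_states)]
    for ages, states in labelings.values():
        seen = set()
        for a, st in zip(ages, states):
            if st not in seen:
                entries[st].append(a)
                seen.add(st)
    return np.array([np.median(e) if e else np.nan for e in entries])


def seroconversion_age(
    series: ParticipantSeries, rule: str = "same_antibody"
) -> float | None:
    """Age of the first of two consecutive visits with persistent positivity.

    ``same_antibody`` (default) requires one antibody positive at both
    visits; ``any_antibody`` requires any positivity at both visits.
    """
    obs = series.obs
    for i in range(len(obs) - 1):
        if rule == "same_antibody":
            hit = np.any((obs[i] == POSITIVE) & (obs[i + 1] == POSITIVE))
        elif rule == "any_antibody":
            hit = np.any(obs[i] == POSITIVE) and np.any(obs[i + 1] == POSITIVE)
        else:
            raise ValueError(f"unknown seroconversion rule {rule!r}")
        if hit:
            return float(series.ages[i])
    return None


def assign_participants(
    labelings: dict, traj_model: TrajectoryModel, cohort=None
) -> list[ParticipantAssignment]:
    """Assign each labeled participant to a chain, or flag as ambiguous.

    ``labelings`` maps participant_id -> (ages, state indices).  If
    ``cohort`` is given (same ids), seroconversion ages are filled in.
    """
    by_id = {s.participant_id: s for s in cohort} if cohort else {}
    out = []
    for pid, (ages, states) in labelings.items():
        states = np.asarray(states)
        touched = {traj_model.chain_of(int(st)) for st in states}
        touched.discard(None)
        chain = touched.pop() if len(touched) == 1 else None
        first_pos = None
        if chain is not None:
            start = traj_model.start_states[chain]
            beyond = np.asarray(ages)[states != start]
            if len(beyond):
                first_pos = float(beyond[0])
        sero = seroconversion_age(by_id[pid]) if pid in by_id else None
        out.append(ParticipantAssignment(
            participant_id=pid,
            chain=chain,
            states=states,
            first_positive_entry_age=first_pos,
            seroconversion_age=sero,
        ))
    return out


def exclusion_counts(assignments) -> dict:
    n_amb = sum(a.ambiguous for a in assignments)
    return {
        "n_total": len(assignments),
        "n_ambiguous": n_amb,
        "n_assigned": len(assignments) - n_amb,
    }


def state_entry_ages(
    assignments, labelings: dict, cohort=None, n_states: int | None = None
) -> pd.DataFrame:
    """Per-state entry/exit age summaries, split by outcome.

    For each state: number of participants entering, median age of first
    and last visit in the state, separately for diagnosed and undiagnosed
    participants (when the cohort is supplied).
    """
    diag = {s.participant_id: s.diagnosed for s in cohort} if cohort else {}
    if n_states is None:
        n_states = 1 + max(int(np.max(st)) for _, st in labelings.values())
    rows = []
    for group in ("all", "diagnosed", "undiagnosed"):
        entry: list[list[float]] = [[] for _ in range(n_states)]
        exit_: list[list[float]] = [[] for _ in range(n_states)]
        for a in assignments:
            if a.ambiguous:
                continue
            pid = a.participant_id
            if group == "diagnosed" and not diag.get(pid, False):
                continue
            if group == "undiagnosed" and diag.get(pid, True):
                continue
            ages, states = labelings[pid]
            ages = np.asarray(ages)
            states = np.asarray(states)
            for st in np.unique(states):
                in_state = ages[states == st]
                entry[int(st)].append(float(in_state[0]))
                exit_[int(st)].append(float(in_state[-1]))
        for st in range(n_states):
            rows.append({
                "state": st,
                "group": group,
                "n_entered": len(entry[st]),
                "median_entry_age": float(np.median(entry[st])) if entry[st] else np.nan,
                "median_exit_age": float(np.median(exit_[st])) if exit_[st] else np.nan,
            })
    return pd.DataFrame(rows)


# The 7 nonzero antibody-positivity patterns as (GADA, IAA, IA-2A) triples.
PATTERNS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1),
]


def pattern_name(p) -> str:
    return "+".join(a.upper() for a, v in zip(ANTIBODIES, p) if v) or "none"


def pattern_by_age(
    assignments, cohort, ages=range(2, 8), n_chains: int = 3
) -> pd.DataFrame:
    """Chain composition of each antibody pattern per integer age bin.

    For each of the 7 positive patterns and each age bin [k, k+1), the
    proportion of pattern-holding (non-ambiguous) participants in each
    chain, plus the denominator count.  A participant contributes once
    per (pattern, bin) in which they have a matching visit.
    """
    chain_of = {a.participant_id: a.chain for a in assignments if not a.ambiguous}
    rows = []
    for p in PATTERNS:
        p_arr = np.array(p)
        for k in ages:
            counts = np.zeros(n_chains)
            seen = set()
            for s in cohort:
                pid = s.participant_id
                if pid not in chain_of or pid in seen:
                    continue
                sel = (s.ages >= k) & (s.ages < k + 1)
                for o in s.obs[sel]:
                    if np.any(o == MISSING):
                        continue
                    if np.array_equal((o == POSITIVE).astype(int), p_arr):
                        counts[chain_of[pid]] += 1
                        seen.add(pid)
                        break
            total = counts.sum()
            row = {
                "pattern": pattern_name(p),
                "age_bin": int(k),
                "n": int(total),
            }
            for c in range(n_chains):
                row[f"prop_tr{c + 1}"] = counts[c] / total if total else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def label_cohort(params: CTHMMParams, cohort, decoding: str = "viterbi") -> dict:
    """Label every participant's visits; returns id -> (ages, states)."""
    from .cthmm import posterior_label, viterbi_label
    from ._kernels import RateEig

    if decoding == "viterbi":
        eig = RateEig(params.rate_matrix)
        return {
            s.participant_id: (s.ages.copy(), viterbi_label(params, s, _eig=eig))
            for s in cohort
        }
    return {
        s.participant_id: (s.ages.copy(), posterior_label(params, s))
        for s in cohort
    }


def assignments_frame(assignments, traj_model: TrajectoryModel) -> pd.DataFrame:
    """Tidy per-participant assignment table (for the CSV interface)."""
    rows = []
    for a in assignments:
        rows.append({
            "participant_id": a.participant_id,
            "chain": "" if a.ambiguous else f"TR{a.chain + 1}",
            "state_sequence": ";".join(traj_model.name(int(s)) for s in a.states),
            "first_positive_entry_age": a.first_positive_entry_age,
            "seroconversion_age": a.seroconversion_age,
            "ambiguous": int(a.ambiguous),
        })
    return pd.DataFrame(rows)
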