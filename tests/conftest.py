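import itertools

import numpy as np
import pytest

from isletraj.cohort import MISSING, ParticipantSeries
from isletraj.cthmm import (
    CTHMMParams,
    emission_likelihood,
    transition_matrix,
)


def random_rate_matrix(n_states: int, rng: np.random.Generator) -> np.ndarray:
    q = rng.exponential(0.8, size=(n_states, n_states))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def random_params(n_states: int, rng: np.random.Generator) -> CTHMMParams:
    pi = rng.dirichlet(np.ones(n_states))
    em = rng.uniform(0.05, 0.95, size=(n_states, 3))
    return CTHMMParams(
        n_states=n_states,
        initial_dist=pi,
        rate_matrix=random_rate_matrix(n_states, rng),
        emissions=em,
    )


def random_series(
    n_visits: int, rng: np.random.Generator, missing_rate: float = 0.2
) -> ParticipantSeries:
    ages = np.sort(rng.uniform(0.3, 10.0, size=n_visits))
    while np.any(np.diff(ages) < 1e-3):
        ages = np.sort(rng.uniform(0.3, 10.0, size=n_visits))
    obs = rng.integers(0, 2, size=(n_visits, 3)).astype(np.int8)
    obs[rng.random(obs.shape) < missing_rate] = MISSING
    return ParticipantSeries(participant_id="x", ages=ages, obs=obs)


def enumerate_loglik(params: CTHMMParams, series: ParticipantSeries) -> float:
    """Brute-force total observation probability over every state path."""
    s = params.n_states
    t = series.n_visits
    kernels = [
        transition_matrix(params.rate_matrix, dt) for dt in np.diff(series.ages)
    ]
    total = 0.0
    for path in itertools.product(range(s), repeat=t):
        p = params.initial_dist[path[0]] * emission_likelihood(
            params.emissions[path[0]], series.obs[0]
        )
        for k in range(1, t):
            p *= kernels[k - 1][path[k - 1], path[k]] * emission_likelihood(
                params.emissions[path[k]], series.obs[k]
            )
        total += p
    return float(np.log(total))


def enumerate_viterbi(params: CTHMMParams, series: ParticipantSeries):
    """Brute-force most probable path (first in lexicographic order wins)."""
    s = params.n_states
    t = series.n_visits
    kernels = [
        transition_matrix(params.rate_matrix, dt) for dt in np.diff(series.ages)
    ]
    best_p, best_path = -1.0, None
    for path in itertools.product(range(s), repeat=t):
        p = params.initial_dist[path[0]] * emission_likelihood(
            params.emissions[path[0]], series.obs[0]
        )
        for k in range(1, t):
            p *= kernels[k - 1][path[k - 1], path[k]] * emission_likelihood(
                params.emissions[path[k]], series.obs[k]
            )
        if p > best_p:
            best_p, best_path = p, path
    return best_p, best_path


@pytest.fixture(scope="session")
def small_cohort():
    """A reproducible 3-state simulated cohort for fitting tests."""
    from isletraj.synthetic import GroundTruthConfig, simulate_cohort

    cfg = GroundTruthConfig(n_participants=120, seed=42)
    sim = simulate_cohort(cfg)
    return [s for s in sim.participants if s.n_visits >= 2]


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulated cohort of 2000 with ground truth."""
    from isletraj.synthetic import GroundTruthConfig, simulate_cohort

    return simulate_cohort(GroundTruthConfig(n_participants=2000, seed=3))


@pytest.fixture(scope="session")
def default_labeled(default_sim):
    """Ground-truth-model labeling and assignment of the default cohort."""
    from isletraj.synthetic import make_ground_truth_model
    from isletraj.trajectories import (
        assign_participants,
        decompose_trajectories,
        label_cohort,
    )

    params = make_ground_truth_model(default_sim.config)
    cohort = default_sim.participants
    labelings = label_cohort(params, cohort)
    tm = decompose_trajectories(params)
    out = assign_participants(labelings, tm, cohort)
    return default_sim, labelings, tm, out
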