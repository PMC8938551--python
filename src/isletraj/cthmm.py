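"""Continuous-time hidden Markov model for irregular binary antibody panels.

The latent health state of a participant evolves as a continuous-time
Markov jump process with rate matrix ``Q``; at each visit (age ``a_t``)
the three islet autoantibodies are observed as independent Bernoulli
variables with state-specific positivity probabilities.  Transition
probabilities over an inter-visit gap ``dt`` are ``expm(Q dt)``, so the
model handles arbitrarily irregular visit schedules.

Parameters are estimated by EM: the E-step runs a scaled forward-backward
pass per participant and accumulates expected dwell times and jump counts
on every inter-visit interval, conditioning on the posterior distribution
of the interval's endpoint states; the M-step has closed forms
(rates = expected jumps / expected dwell, emissions = posterior-weighted
positive fractions, initial distribution = normalised first-visit
posteriors).

The public surface is :class:`CTHMM`, a scikit-learn style estimator
(``fit`` / ``predict`` / ``score``), plus thin module-level functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _kernels
from ._kernels import endpoint_conditioned_stats, transition_matrix  # noqa: F401
from .cohort import (
    MISSING,
    N_ANTIBODIES,
    POSITIVE,
    PackedCohort,
    ParticipantSeries,
    pack_cohort,
)

MAX_STATES = 40
_EMISSION_CLIP = 1e-6
_RATE_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# parameter container


@dataclass
class CTHMMParams:
    """Model parameters: initial distribution, rate matrix, emissions."""

    n_states: int
    initial_dist: np.ndarray
    rate_matrix: np.ndarray
    emissions: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.validate()

    def validate(self) -> None:
        s = self.n_states
        if self.initial_dist.shape != (s,):
            raise ValueError("initial_dist has wrong shape")
        if abs(self.initial_dist.sum() - 1.0) > 1e-10 or np.any(self.initial_dist < 0):
            raise ValueError("initial_dist must be a probability vector")
        if self.rate_matrix.shape != (s, s):
            raise ValueError("rate_matrix has wrong shape")
        _kernels.validate_rate_matrix(self.rate_matrix)
        if self.emissions.shape != (s, N_ANTIBODIES):
            raise ValueError(
                f"emissions must have shape ({s}, {N_ANTIBODIES})"
            )
        if np.any(self.emissions < 0) or np.any(self.emissions > 1):
            raise ValueError("emission probabilities must lie in [0, 1]")

    def to_json(self) -> str:
        payload = {
            "n_states": self.n_states,
            "initial_dist": [float(x) for x in self.initial_dist],
            "rate_matrix": [float(x) for x in self.rate_matrix.ravel()],
            "emissions": [float(x) for x in self.emissions.ravel()],
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CTHMMParams":
        d = json.loads(text)
        s = d["n_states"]
        return cls(
            n_states=s,
            initial_dist=np.array(d["initial_dist"]),
            rate_matrix=np.array(d["rate_matrix"]).reshape(s, s),
            emissions=np.array(d["emissions"]).reshape(s, N_ANTIBODIES),
            metadata=d.get("metadata", {}),
        )


@dataclass
class SufficientStats:
    """E-step accumulator."""

    expected_dwell: np.ndarray
    expected_jumps: np.ndarray
    emission_pos_weight: np.ndarray
    emission_obs_weight: np.ndarray
    initial_weight: np.ndarray
    total_loglik: float


@dataclass
class FitResult:
    params: CTHMMParams
    loglik_trace: list
    n_iter: int
    converged: bool
    seed: int | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


# ---------------------------------------------------------------------------
# likelihood machinery


def emission_likelihood(emission_row: np.ndarray, obs) -> float:
    """P(observation triple | state): product over non-missing antibodies."""
    p = np.asarray(emission_row, dtype=float)
    o = np.asarray(obs)
    like = 1.0
    for j in range(N_ANTIBODIES):
        if o[j] == MISSING:
            continue
        like *= p[j] if o[j] == POSITIVE else 1.0 - p[j]
    return float(like)


def _emission_matrix(emissions: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Batched emission likelihoods: obs (N, T, 3) -> (N, T, S)."""
    p = emissions.T[None, None]                  # (1, 1, 3, S)
    x = obs[..., None].astype(float)             # (N, T, 3, 1)
    terms = np.where(x == POSITIVE, p, np.where(x == MISSING, 1.0, 1.0 - p))
    return terms.prod(axis=2)


def _forward_backward_packed(
    params: CTHMMParams, packed: PackedCohort, eig: _kernels.RateEig | None = None
):
    """Scaled forward-backward over all participants at once.

    Returns per-visit posteriors ``gamma`` (N, T, S), per-interval
    endpoint-pair posteriors ``xi`` (N, T-1, S, S), per-participant
    log-likelihoods (N,), and the batch of transition matrices (N, T-1, S, S).
    Padded visits are all-missing with dt = 0, so they contribute factor 1
    and identity kernels and leave every quantity unchanged.
    """
    n, t_max = packed.ages.shape
    s = params.n_states
    eig = eig or _kernels.RateEig(params.rate_matrix)
    # gaps repeat heavily (ages carry 3-decimal precision), so kernels are
    # computed once per distinct gap and gathered back
    uniq_dt, inv_dt = np.unique(packed.dt.ravel(), return_inverse=True)
    pmats = eig.transition_batch(uniq_dt)[inv_dt].reshape(n, t_max - 1, s, s)
    b = _emission_matrix(params.emissions, packed.obs)        # (N, T, S)

    alpha = np.empty((n, t_max, s))
    c = np.empty((n, t_max))
    a = params.initial_dist[None, :] * b[:, 0]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] <= 0):
        raise FloatingPointError("zero likelihood at first visit")
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, t_max):
        a = np.einsum("ni,nij->nj", alpha[:, t - 1], pmats[:, t - 1]) * b[:, t]
        c[:, t] = a.sum(axis=1)
        if np.any(c[:, t] <= 0):
            raise FloatingPointError("zero likelihood during forward pass")
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((n, t_max, s))
    beta[:, -1] = 1.0
    for t in range(t_max - 2, -1, -1):
        m = b[:, t + 1] * beta[:, t + 1]
        beta[:, t] = np.einsum("nij,nj->ni", pmats[:, t], m) / c[:, t + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    xi = (
        alpha[:, :-1, :, None]
        * pmats
        * (b[:, 1:] * beta[:, 1:])[:, :, None, :]
        / c[:, 1:, None, None]
    )

    loglik = np.where(packed.mask, np.log(c), 0.0).sum(axis=1)
    return gamma, xi, loglik, pmats, eig, (uniq_dt, inv_dt)


def forward_backward(params: CTHMMParams, series: ParticipantSeries):
    """Posterior state marginals, endpoint-pair posteriors, and loglik."""
    packed = pack_cohort([series])
    gamma, xi, loglik, *_ = _forward_backward_packed(params, packed)
    return gamma[0], xi[0], float(loglik[0])


def loglik_dataset(params: CTHMMParams, cohort) -> tuple[float, int]:
    """Total log-likelihood of a cohort and its total visit count."""
    packed = cohort if isinstance(cohort, PackedCohort) else pack_cohort(cohort)
    loglik = _forward_backward_packed(params, packed)[2]
    return float(loglik.sum()), packed.total_visits


def _e_step(params: CTHMMParams, packed: PackedCohort) -> SufficientStats:
    n, t_max = packed.ages.shape
    s = params.n_states
    gamma, xi, loglik, pmats, eig, (uniq_dt, inv_dt) = _forward_backward_packed(
        params, packed
    )

    # endpoint-pair weights divided by transition probabilities, pooled per
    # distinct gap (dwell/jump integrals are linear in the weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(pmats > 0, xi / pmats, 0.0)
    w_by_dt = np.zeros((len(uniq_dt), s, s))
    np.add.at(w_by_dt, inv_dt, w.reshape(-1, s, s))
    dwell_g, jumps_g = eig.interval_stats_batch(uniq_dt, w_by_dt)
    dwell = dwell_g.sum(axis=0)
    jumps = jumps_g.sum(axis=0)

    observed = packed.obs != MISSING                          # (N, T, 3)
    positive = packed.obs == POSITIVE
    pos_w = np.einsum("nts,ntj->sj", gamma, positive.astype(float))
    obs_w = np.einsum("nts,ntj->sj", gamma, observed.astype(float))
    return SufficientStats(
        expected_dwell=dwell,
        expected_jumps=jumps,
        emission_pos_weight=pos_w,
        emission_obs_weight=obs_w,
        initial_weight=gamma[:, 0].sum(axis=0),
        total_loglik=float(loglik.sum()),
    )


def _m_step(
    stats: SufficientStats, n_states: int, emission_pseudocount: float = 0.0
) -> CTHMMParams:
    s = n_states
    dwell = stats.expected_dwell
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(dwell[:, None] > 0, stats.expected_jumps / dwell[:, None], 0.0)
    np.fill_diagonal(q, 0.0)
    # keep the kernel well-defined when a state accrues no dwell time
    q[(dwell <= 0)[:, None] & ~np.eye(s, dtype=bool)] = _RATE_FLOOR
    np.fill_diagonal(q, -q.sum(axis=1) + np.diag(q))
    pi = stats.initial_weight / stats.initial_weight.sum()
    a = emission_pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        em = (stats.emission_pos_weight + a) / (stats.emission_obs_weight + 2 * a)
        em = np.where(
            stats.emission_obs_weight + 2 * a > 0, em, 0.5
        )
    em = np.clip(em, _EMISSION_CLIP, 1.0 - _EMISSION_CLIP)
    return CTHMMParams(
        n_states=s, initial_dist=pi, rate_matrix=q, emissions=em
    )


def _emission_log_prior(em: np.ndarray, a: float) -> float:
    if a <= 0:
        return 0.0
    return float(a * (np.log(em) + np.log1p(-em)).sum())


def _random_rates_pi(n_states: int, rng: np.random.Generator):
    s = n_states
    c = np.exp(rng.uniform(np.log(0.05), np.log(1.0), size=s))
    q = np.tile((c / s)[:, None], (1, s))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    pi = rng.dirichlet(np.ones(s))
    return q, pi


def _random_init(n_states: int, rng: np.random.Generator) -> CTHMMParams:
    s = n_states
    em = rng.uniform(0.05, 0.95, size=(s, N_ANTIBODIES))
    q, pi = _random_rates_pi(s, rng)
    return CTHMMParams(n_states=s, initial_dist=pi, rate_matrix=q, emissions=em)


def _kmeans_init(
    packed: PackedCohort, n_states: int, rng: np.random.Generator
) -> CTHMMParams:
    """Cluster visit observation vectors to seed the emission rows.

    Missing antibody values are imputed with the observed column mean for
    the clustering only; cluster positivity fractions (slightly jittered,
    so restarts differ) become the initial emissions.  Rates and the
    initial distribution are drawn as in the random initialisation.
    """
    from sklearn.cluster import KMeans

    s = n_states
    obs = packed.obs[packed.mask]
    x = obs.astype(float)
    for j in range(N_ANTIBODIES):
        col = obs[:, j]
        observed = col != MISSING
        mean = col[observed].mean() if observed.any() else 0.5
        x[~observed, j] = mean
    km = KMeans(
        n_clusters=min(s, len(x)), n_init=3,
        random_state=int(rng.integers(2**31)),
    ).fit(x)
    em = np.empty((s, N_ANTIBODIES))
    for k in range(s):
        sel = obs[km.labels_ == k] if k < km.n_clusters else obs[:0]
        for j in range(N_ANTIBODIES):
            v = sel[:, j][sel[:, j] != MISSING] if len(sel) else []
            em[k, j] = np.mean(v) if len(v) else rng.uniform(0.05, 0.95)
    em = np.clip(em + rng.normal(0.0, 0.02, size=em.shape), 0.02, 0.98)
    q, pi = _random_rates_pi(s, rng)
    return CTHMMParams(n_states=s, initial_dist=pi, rate_matrix=q, emissions=em)


def _em_single(
    packed: PackedCohort,
    init: CTHMMParams,
    tol: float,
    max_iter: int,
    emission_pseudocount: float = 0.0,
) -> tuple[CTHMMParams, list, bool]:
    """One EM run.  The trace holds the maximised objective: the data
    log-likelihood plus (when smoothing is on) the Beta log-prior of the
    emissions, which EM increases monotonically."""
    params = init
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        stats = _e_step(params, packed)
        trace.append(
            stats.total_loglik
            + _emission_log_prior(params.emissions, emission_pseudocount)
        )
        new_params = _m_step(stats, params.n_states, emission_pseudocount)
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                params = new_params
                break
        params = new_params
    return params, trace, converged


def em_fit(
    dataset,
    n_states: int,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    init: str = "kmeans",
    emission_pseudocount: float = 0.5,
) -> FitResult:
    """Fit a CT-HMM by EM with restarts; returns the best restart.

    ``dataset`` is a sequence of :class:`ParticipantSeries` (or a
    ``PackedCohort``); every series needs at least 2 visits.

    ``init="kmeans"`` (default) seeds each restart's emission rows from a
    k-means clustering of the visit observation vectors, jittered so
    restarts differ; ``init="random"`` draws emissions uniform on
    (0.05, 0.95).  Rates start row-constant with a log-uniform scale in
    both schemes.

    ``emission_pseudocount`` applies a symmetric Beta(1+a, 1+a) prior to
    every emission probability (MAP M-step), guarding against degenerate
    states that pin emissions at 0/1 to fit a handful of visits; the
    default a=0.5 (Jeffreys-style) shifts well-populated states by less
    than 0.3%.  Set 0 for plain maximum likelihood.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states > MAX_STATES:
        raise ValueError(f"n_states exceeds the cap of {MAX_STATES}")
    packed = dataset if isinstance(dataset, PackedCohort) else pack_cohort(
        [s.merge_duplicate_ages() for s in dataset]
    )
    if np.any(packed.n_visits < 2):
        raise ValueError("every participant needs >= 2 visits for fitting")
    if init not in ("kmeans", "random"):
        raise ValueError(f"unknown init scheme {init!r}")
    rng = np.random.default_rng(seed)
    best: tuple[CTHMMParams, list, bool] | None = None
    for _ in range(max(1, n_restarts)):
        start = (
            _kmeans_init(packed, n_states, rng)
            if init == "kmeans"
            else _random_init(n_states, rng)
        )
        fitted, trace, conv = _em_single(
            packed, start, tol, max_iter, emission_pseudocount
        )
        if best is None or trace[-1] > best[1][-1]:
            best = (fitted, trace, conv)
    params, trace, conv = best
    from . import __version__

    params.metadata.update(
        {"seed": seed, "loglik": trace[-1], "n_iter": len(trace),
         "version": __version__}
    )
    return FitResult(
        params=params,
        loglik_trace=trace,
        n_iter=len(trace),
        converged=conv,
        seed=seed,
    )


def viterbi_label(
    params: CTHMMParams,
    series: ParticipantSeries,
    _eig: "_kernels.RateEig | None" = None,
) -> np.ndarray:
    """Most probable joint state path; ties resolve to the lower index."""
    s = params.n_states
    ages, obs = series.ages, series.obs
    t_max = len(ages)
    with np.errstate(divide="ignore"):
        logb = np.log(
            _emission_matrix(params.emissions, obs[None])[0]
        )                                                        # (T, S)
        logpi = np.log(params.initial_dist)
    eig = _eig or _kernels.RateEig(params.rate_matrix)
    pmats = eig.transition_batch(np.diff(ages))
    delta = logpi + logb[0]
    back = np.zeros((t_max, s), dtype=int)
    with np.errstate(divide="ignore"):
        logp = np.log(pmats)
    for t in range(1, t_max):
        cand = delta[:, None] + logp[t - 1]                      # (S, S)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(s)] + logb[t]
    path = np.zeros(t_max, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_max - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def posterior_label(params: CTHMMParams, series: ParticipantSeries) -> np.ndarray:
    """Maximum-posterior-marginal state per visit (alternative to Viterbi)."""
    gamma, _, _ = forward_backward(params, series)
    return np.argmax(gamma, axis=1)


def bic(loglik: float, n_states: int, n_visits: int) -> float:
    """Bayesian Information Criterion with the visit-count convention.

    Free parameters: (S-1) initial probabilities, S(S-1) off-diagonal
    rates, 3S emission probabilities.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    s = n_states
    k = (s - 1) + s * (s - 1) + N_ANTIBODIES * s
    return -2.0 * loglik + k * np.log(n_visits)


# ---------------------------------------------------------------------------
# estimator


class CTHMM(BaseEstimator):
    """Continuous-time hidden Markov model estimator.

    Parameters
    ----------
    n_states : int, default 11
        Number of latent states.
    n_restarts : int, default 5
        Independent EM runs from random initialisations; the best final
        log-likelihood wins.
    tol : float, default 1e-6
        Relative log-likelihood change declaring convergence.
    max_iter : int, default 500
        EM iteration cap per restart.
    random_state : int or None
        Seed for the restart initialisations.
    decoding : {"viterbi", "posterior"}, default "viterbi"
        State-labelling rule used by :meth:`predict`.

    Attributes
    ----------
    initial_dist_ : (S,) ndarray
    rate_matrix_ : (S, S) ndarray
    emissions_ : (S, 3) ndarray
    loglik_trace_ : list of float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_states: int = 11,
        n_restarts: int = 5,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int | None = None,
        decoding: str = "viterbi",
        init: str = "kmeans",
        emission_pseudocount: float = 0.5,
    ):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.decoding = decoding
        self.init = init
        self.emission_pseudocount = emission_pseudocount

    def fit(self, X, y=None) -> "CTHMM":
        """Fit to a cohort (sequence of :class:`ParticipantSeries`)."""
        result = em_fit(
            X,
            n_states=self.n_states,
            n_restarts=self.n_restarts,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.random_state,
            init=self.init,
            emission_pseudocount=self.emission_pseudocount,
        )
        self.params_ = result.params
        self.initial_dist_ = result.params.initial_dist
        self.rate_matrix_ = result.params.rate_matrix
        self.emissions_ = result.params.emissions
        self.loglik_trace_ = result.loglik_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.fit_result_ = result
        return self

    def _check_fitted(self) -> CTHMMParams:
        if not hasattr(self, "params_"):
            raise AttributeError("this CTHMM instance is not fitted yet")
        return self.params_

    def predict(self, X) -> list:
        """Per-visit state labels for each series in the cohort."""
        params = self._check_fitted()
        label = viterbi_label if self.decoding == "viterbi" else posterior_label
        return [label(params, s) for s in X]

    def predict_proba(self, X) -> list:
        """Per-visit posterior state marginals for each series."""
        params = self._check_fitted()
        return [forward_backward(params, s)[0] for s in X]

    def score(self, X, y=None) -> float:
        """Mean per-visit log-likelihood of a cohort."""
        total, n_visits = loglik_dataset(self._check_fitted(), X)
        return total / n_visits

    def bic(self, X) -> float:
        """BIC of the fitted model on a cohort (visit-count convention)."""
        total, n_visits = loglik_dataset(self._check_fitted(), X)
        return bic(total, self.n_states, n_visits)
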