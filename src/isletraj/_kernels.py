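"""Linear-algebra kernels for continuous-time Markov chains.

Two routes to the endpoint-conditioned sufficient statistics (expected
dwell times and jump counts over an interval of length ``dt`` given the
states at both ends):

* a per-interval construction via the augmented matrix exponential
  (Van Loan block trick): for a rate matrix ``Q`` and unit matrix
  ``E_kl``, the upper-right block of ``expm([[Q, E_kl], [0, Q]] * dt)``
  equals ``integral_0^dt expm(Q s) E_kl expm(Q (dt-s)) ds``;
* a batched closed form through the eigendecomposition ``Q = U diag(lam)
  U^-1``, where the same integral reduces to a Hadamard product with the
  matrix ``J_pq = (exp(lam_p dt) - exp(lam_q dt)) / (lam_p - lam_q)``.

The EM driver uses the batched route; the per-interval route backs the
public API and serves as an internal cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

_EIG_RECON_TOL = 1e-7


def validate_rate_matrix(rate_matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check off-diagonals >= 0 and row sums ~ 0; return a float array."""
    q = np.asarray(rate_matrix, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("rate matrix must be square")
    off = q - np.diag(np.diag(q))
    if np.any(off < -tol):
        raise ValueError("rate matrix has negative off-diagonal entries")
    scale = max(1.0, np.abs(q).max())
    if np.any(np.abs(q.sum(axis=1)) > tol * scale * q.shape[0]):
        raise ValueError("rate matrix rows must sum to 0")
    return q


def transition_matrix(rate_matrix: np.ndarray, dt: float) -> np.ndarray:
    """Transition probabilities over a gap of ``dt`` years: ``expm(Q dt)``."""
    q = validate_rate_matrix(rate_matrix)
    if dt < 0:
        raise ValueError("dt must be >= 0")
    p = expm(q * dt)
    p = np.clip(p, 0.0, 1.0)
    return p / p.sum(axis=1, keepdims=True)


class RateEig:
    """Eigendecomposition of a rate matrix with a conditioning guard.

    Nearly defective matrices are jittered (tiny relative perturbation of
    the off-diagonal entries) until the decomposition reconstructs ``Q``
    to within ``_EIG_RECON_TOL``; the perturbation is far below the
    statistical precision of any EM step.
    """

    def __init__(self, rate_matrix: np.ndarray, rng: np.random.Generator | None = None):
        q = np.asarray(rate_matrix, dtype=float)
        scale = max(np.abs(q).max(), 1e-12)
        rng = rng or np.random.default_rng(0)
        jitter = 0.0
        for attempt in range(4):
            qj = q
            if jitter > 0:
                noise = rng.uniform(0.5, 1.5, size=q.shape) * jitter * scale
                off = np.maximum(q - np.diag(np.diag(q)) + noise, 0.0)
                qj = off - np.diag(off.sum(axis=1))
            lam, u = np.linalg.eig(qj)
            try:
                v = np.linalg.inv(u)
            except np.linalg.LinAlgError:
                jitter = 10.0 ** (attempt - 9)
                continue
            recon = (u * lam) @ v
            if np.abs(recon - qj).max() <= _EIG_RECON_TOL * max(scale, 1.0):
                break
            jitter = 10.0 ** (attempt - 9)
        if np.abs(lam.imag).max() <= 1e-12 * max(scale, 1.0):
            lam, u, v = lam.real, u.real, v.real
        self.q = qj
        self.lam = lam
        self.u = u
        self.v = v

    def transition_batch(self, dt: np.ndarray) -> np.ndarray:
        """Transition matrices for a vector of gaps; shape (M, S, S)."""
        dt = np.asarray(dt, dtype=float)
        e = np.exp(self.lam[None, :] * dt[:, None])          # (M, S)
        p = (self.u[None, :, :] * e[:, None, :]) @ self.v    # (M, S, S)
        p = np.clip(p.real, 0.0, 1.0)
        s = p.sum(axis=2, keepdims=True)
        return p / np.where(s > 0, s, 1.0)

    def _j_matrix(self, dt: np.ndarray) -> np.ndarray:
        """J_pq = (e^{lam_p t} - e^{lam_q t}) / (lam_p - lam_q), batched."""
        lam = self.lam
        t = dt[:, None, None]
        dl = lam[None, :, None] - lam[None, None, :]
        el = np.exp(lam[None, :] * dt[:, None])              # (M, S)
        num = el[:, :, None] - el[:, None, :]
        close = np.abs(dl) < 1e-10 * (1.0 + np.abs(lam).max())
        j = np.where(close, t * el[:, :, None], num / np.where(close, 1.0, dl))
        return j

    def interval_stats_batch(
        self, dt: np.ndarray, weights: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior-weighted dwell and jump expectations per interval.

        Parameters
        ----------
        dt : (M,) gaps.
        weights : (M, S, S)
            Per-interval endpoint-pair posterior weights already divided by
            the corresponding transition probabilities (zero where the
            transition probability is zero).

        Returns
        -------
        dwell : (M, S) expected time in each state.
        jumps : (M, S, S) expected transition counts (zero diagonal).
        """
        u, v = self.u, self.v
        j = self._j_matrix(dt)                               # (M, S, S)
        m = u.T @ weights.astype(u.dtype) @ v.T              # (M, S, S)
        k = v.T @ (m * j) @ u.T                              # (M, S, S)
        kr = k.real if np.iscomplexobj(k) else k
        dwell = np.maximum(np.einsum("mkk->mk", kr), 0.0)
        q_off = self.q - np.diag(np.diag(self.q))
        jumps = np.maximum(q_off[None, :, :] * kr, 0.0)
        np.einsum("mkk->mk", jumps)[:] = 0.0
        return dwell, jumps


def integral_expm(rate_matrix: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """``integral_0^dt expm(Q s) B expm(Q (dt-s)) ds`` by the block trick."""
    q = np.asarray(rate_matrix, dtype=float)
    s = q.shape[0]
    aug = np.zeros((2 * s, 2 * s))
    aug[:s, :s] = q
    aug[s:, s:] = q
    aug[:s, s:] = b
    return expm(aug * dt)[:s, s:]


def endpoint_conditioned_stats(
    rate_matrix: np.ndarray, dt: float, start: int, end: int
) -> tuple[np.ndarray, np.ndarray]:
    """Expected dwell times and jump counts conditioned on both endpoints.

    Conditions a continuous-time Markov chain with generator
    ``rate_matrix`` on being in ``start`` at time 0 and ``end`` at time
    ``dt`` and returns the expected time spent in each state and the
    expected count of each jump.

    Raises
    ------
    ValueError
        If the transition probability start -> end over ``dt`` is zero.
    """
    q = validate_rate_matrix(rate_matrix)
    s = q.shape[0]
    p = transition_matrix(q, dt)
    p_ij = p[start, end]
    if p_ij <= 0:
        raise ValueError(
            f"conditioning on a zero-probability endpoint pair "
            f"({start} -> {end} over dt={dt})"
        )
    dwell = np.zeros(s)
    jumps = np.zeros((s, s))
    for k in range(s):
        e = np.zeros((s, s))
        e[k, k] = 1.0
        dwell[k] = integral_expm(q, e, dt)[start, end] / p_ij
        for l in range(s):
            if l == k or q[k, l] <= 0:
                continue
            e = np.zeros((s, s))
            e[k, l] = 1.0
            jumps[k, l] = q[k, l] * integral_expm(q, e, dt)[start, end] / p_ij
    return np.maximum(dwell, 0.0), np.maximum(jumps, 0.0)
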