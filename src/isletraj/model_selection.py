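"""Model-order search by repeated participant-level splits.

For every candidate state count and replicate, the cohort is split
70:30 at the participant level (a participant's entire visit history is
either training or held-out, never both), the model is fit on the
training split, and two scores are recorded: the BIC of the training fit
and the per-visit predictive log-likelihood of the held-out split.  The
winning order minimises mean BIC up to a small band and, within the
band, maximises mean held-out predictive log-likelihood.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cthmm import CTHMM, FitResult, bic, em_fit, loglik_dataset

log = logging.getLogger("isletraj")

TABLE_COLUMNS = [
    "n_states", "replicate", "seed", "train_loglik",
    "heldout_loglik_per_visit", "bic",
]


def split_participants(
    cohort, split_fraction: float, rng: np.random.Generator
) -> tuple[list, list]:
    """Random participant-level train/held-out split."""
    n = len(cohort)
    n_train = int(round(split_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("dataset too small to split at this fraction")
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [cohort[i] for i in range(n) if i in train_idx]
    test = [cohort[i] for i in range(n) if i not in train_idx]
    return train, test


def run_experiments(
    dataset,
    state_range,
    n_reps: int = 100,
    split_fraction: float = 0.7,
    seed: int | None = None,
    n_restarts: int = 2,
    tol: float = 1e-4,
    max_iter: int = 200,
    fits: dict | None = None,
) -> pd.DataFrame:
    """Fit every (state count, replicate) cell of the model-order search.

    Returns a table with one row per cell: training log-likelihood, BIC on
    the training split, and per-visit predictive log-likelihood on the
    held-out split.  Each cell derives its own seed from ``seed`` so rows
    are independent and the whole table is reproducible.  If ``fits`` is a
    dict it collects the per-cell :class:`FitResult` objects keyed by
    ``(n_states, replicate)``.
    """
    state_range = list(state_range)
    if not state_range:
        raise ValueError("state_range is empty")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie in (0, 1)")
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, rep_seq in enumerate(root.spawn(int(n_reps))):
        split_seed, fit_seed = rep_seq.generate_state(2) >> 1  # keep < 2**31
        rng = np.random.default_rng(int(split_seed))
        train, test = split_participants(dataset, split_fraction, rng)
        for s in state_range:
            cell_seed = int((fit_seed + 1000003 * s) % (2**31))
            result = em_fit(
                train, n_states=s, n_restarts=n_restarts,
                tol=tol, max_iter=max_iter, seed=cell_seed,
            )
            _, n_train_visits = loglik_dataset(result.params, train)
            heldout_ll, n_test_visits = loglik_dataset(result.params, test)
            rows.append({
                "n_states": s,
                "replicate": rep,
                "seed": cell_seed,
                "train_loglik": result.loglik,
                "heldout_loglik_per_visit": heldout_ll / n_test_visits,
                "bic": bic(result.loglik, s, n_train_visits),
            })
            if fits is not None:
                fits[(s, rep)] = result
            log.info(
                "selection cell S=%d rep=%d: train ll %.1f, heldout/visit %.4f",
                s, rep, result.loglik, heldout_ll / n_test_visits,
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def select_model(
    table: pd.DataFrame,
    dataset=None,
    bic_band: float = 0.01,
    refit_kwargs: dict | None = None,
) -> tuple[int, FitResult | None]:
    """Choose the state count and (optionally) refit on the full dataset.

    Candidates are the state counts whose mean BIC lies within
    ``bic_band`` (a fraction of the BIC range across orders, default 1%)
    of the minimum mean BIC; the winner has the highest mean held-out
    per-visit log-likelihood among candidates.  If ``dataset`` is given,
    the winning order is refit on it with full restarts.
    """
    if len(table) == 0:
        raise ValueError("empty model-selection table")
    means = table.groupby("n_states")[["bic", "heldout_loglik_per_visit"]].mean()
    bic_min = means["bic"].min()
    bic_range = means["bic"].max() - bic_min
    band = bic_band * bic_range if bic_range > 0 else 0.0
    candidates = means[means["bic"] <= bic_min + band]
    chosen = int(candidates["heldout_loglik_per_visit"].idxmax())
    refit = None
    if dataset is not None:
        kwargs = dict(n_restarts=5, tol=1e-6, max_iter=500, seed=0)
        kwargs.update(refit_kwargs or {})
        refit = em_fit(dataset, n_states=chosen, **kwargs)
    return chosen, refit


def selection_report(table: pd.DataFrame, chosen: int) -> dict:
    """JSON-serialisable summary of the model-order search."""
    means = table.groupby("n_states")[["bic", "heldout_loglik_per_visit"]].mean()
    return {
        "chosen_n_states": chosen,
        "n_rows": int(len(table)),
        "mean_bic": {int(k): float(v) for k, v in means["bic"].items()},
        "mean_heldout_loglik_per_visit": {
            int(k): float(v)
            for k, v in means["heldout_loglik_per_visit"].items()
        },
    }
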