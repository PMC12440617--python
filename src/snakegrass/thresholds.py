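"""Threshold re-estimation, bootstrap reliability, and the exclusion filter.

After data collection, all non-warm-up trials of a participant x condition
cell (both polarity staircases pooled, 80-160 trials) are replayed through a
running fit identical to the one that controlled contrast online, and the
81%-correct threshold is read off the final fit.  A nonparametric
case-resampling bootstrap attaches a standard error; estimates whose SE
exceeds 0.2 (contrast units) are flagged unreliable and excluded from
inference.  Because the running fit sums independent per-trial log
likelihoods, the estimate is invariant to trial order, which also lets the
bootstrap be computed with one matrix product per cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .staircase import (
    CONTRAST_MAX,
    CONTRAST_MIN,
    THRESHOLD_CRITERION,
    WeibullPF,
    alpha_grid,
    threshold_from_pf,
)

SE_EXCLUSION = 0.2


def _loglik_matrix(
    contrasts: np.ndarray, correct: np.ndarray, grid: np.ndarray,
    beta: float = 3.5, gamma: float = 0.5, lapse: float = 0.02,
) -> np.ndarray:
    """(n_trials, n_grid) Bernoulli log likelihoods under alpha = grid."""
    p = gamma + (1.0 - gamma - lapse) * (
        1.0 - np.exp(-((contrasts[:, None] / grid[None, :]) ** beta))
    )
    return np.where(correct[:, None], np.log(p), np.log1p(-p))


def _threshold_from_alpha(alpha: float, beta: float = 3.5, lapse: float = 0.02) -> float:
    return threshold_from_pf(WeibullPF(alpha=alpha, beta=beta, lapse=lapse), THRESHOLD_CRITERION)


def refit_threshold(
    contrasts: np.ndarray | list, correct: np.ndarray | list,
    beta: float = 3.5, lapse: float = 0.02,
) -> float:
    """Pooled running-fit threshold at the 81% criterion.

    Replays the trial multiset (order is irrelevant) through a fresh running
    fit and inverts the final Weibull at the criterion.  Ties in the grid
    likelihood break toward lower contrast.  The returned threshold can
    exceed the displayable maximum when the observer underperforms the
    criterion even at full contrast.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if len(contrasts) == 0:
        raise ValueError("cannot refit a threshold from zero trials")
    grid = alpha_grid()
    ll = _loglik_matrix(contrasts, correct, grid, beta=beta, lapse=lapse).sum(axis=0)
    alpha = float(grid[int(np.argmax(ll))])
    return _threshold_from_alpha(alpha, beta=beta, lapse=lapse)


def bootstrap_se(
    contrasts: np.ndarray | list, correct: np.ndarray | list,
    B: int = 250, rng: np.random.Generator | int | None = None,
    beta: float = 3.5, lapse: float = 0.02,
) -> float:
    """Case-resampling bootstrap SE of the refit threshold (contrast units)."""
    contrasts = np.asarray(contrasts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    n = len(contrasts)
    if n < 10:
        raise ValueError("bootstrap needs at least 10 trials")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = alpha_grid()
    ll = _loglik_matrix(contrasts, correct, grid, beta=beta, lapse=lapse)
    # multinomial resample counts (B, n) @ (n, grid) = per-resample likelihoods
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
    ll_boot = counts @ ll
    alphas = grid[np.argmax(ll_boot, axis=1)]
    thresholds = np.array([_threshold_from_alpha(a, beta=beta, lapse=lapse) for a in alphas])
    return float(np.std(thresholds, ddof=1))


def estimate_thresholds(
    trials: pd.DataFrame, B: int = 250, rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per participant x condition thresholds with bootstrap SEs.

    ``trials`` is the experiment trial table; warm-up trials are dropped and
    both polarity staircases pooled.  Returns one row per cell with columns
    participant_id, eccentricity, spacing, wiggle, threshold, bootstrap_se,
    n_trials, reliable.  Reported thresholds are clipped to the displayable
    range [0.001, 0.95]; the bootstrap SE is computed from the unclipped
    resample spread, which is what flags non-converging cells.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    data = trials.loc[~trials["is_warmup"]]
    rows = []
    keys = ["participant_id", "eccentricity", "spacing", "wiggle"]
    for (pid, ecc, spa, wig), g in data.groupby(keys, sort=True):
        c = g["contrast"].to_numpy()
        k = g["correct"].to_numpy()
        thr = refit_threshold(c, k)
        se = bootstrap_se(c, k, B=B, rng=rng)
        rows.append(
            {
                "participant_id": pid,
                "eccentricity": ecc,
                "spacing": spa,
                "wiggle": wig,
                "threshold": float(np.clip(thr, CONTRAST_MIN, CONTRAST_MAX)),
                "bootstrap_se": se,
                "n_trials": len(g),
                "reliable": se <= SE_EXCLUSION,
            }
        )
    return pd.DataFrame(rows)


def filter_reliable(estimates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the SE > 0.2 exclusion; report per-condition reliability.

    Returns the kept estimates and a table of the proportion of participants
    with a reliable threshold in each (eccentricity, spacing, wiggle) cell.
    """
    kept = estimates.loc[estimates["bootstrap_se"] <= SE_EXCLUSION].copy()
    props = (
        estimates.groupby(["eccentricity", "spacing", "wiggle"], sort=True)["reliable"]
        .mean()
        .rename("proportion_reliable")
        .reset_index()
    )
    return kept, props
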