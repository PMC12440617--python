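"""Adaptive 2AFC contrast control: running-fit Weibull staircases.

The task is spatial two-alternative forced choice (snake left or right of
fixation, guess rate 0.5).  Contrast on each trial is placed at the current
maximum-likelihood threshold estimate of a Weibull psychometric function
whose slope, guess and lapse rates are held fixed at their seed values; only
the threshold parameter alpha is tracked, on a log-spaced contrast grid.
After each trial the Bernoulli log likelihood of the observed outcome is
added to the running per-grid-point total ("running fit").

Thresholds are reported at the 81%-correct criterion via analytic inversion
of the psychometric function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

from .geometry import Condition, Side

CONTRAST_MIN = 0.001
CONTRAST_MAX = 0.95
#: The threshold parameter is searched beyond the displayable contrast range:
#: observers who cannot do the task at maximum contrast have their ML alpha
#: far above it, and capping the grid at the display maximum would silently
#: squash the bootstrap spread of exactly those estimates.  Contrast
#: *placement* is always clamped to [CONTRAST_MIN, CONTRAST_MAX].
ALPHA_MAX = 4.0
GRID_SIZE = 151
THRESHOLD_CRITERION = 0.81


@dataclass(frozen=True)
class WeibullPF:
    """Weibull psychometric function P(correct) for a 2AFC task.

    ``P(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x / alpha)^beta))``
    """

    alpha: float
    beta: float = 3.5
    gamma: float = 0.5
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")


def pf_eval(pf: WeibullPF, x: float | np.ndarray) -> float | np.ndarray:
    """Probability correct at contrast ``x`` (> 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("contrast must be positive")
    p = pf.gamma + (1.0 - pf.gamma - pf.lapse) * (1.0 - np.exp(-((x / pf.alpha) ** pf.beta)))
    return float(p) if p.ndim == 0 else p


def threshold_from_pf(pf: WeibullPF, criterion: float = THRESHOLD_CRITERION) -> float:
    """Contrast at which ``pf`` reaches ``criterion`` proportion correct."""
    if not pf.gamma < criterion < 1.0 - pf.lapse:
        raise ValueError(f"criterion must lie in ({pf.gamma}, {1 - pf.lapse})")
    q = (criterion - pf.gamma) / (1.0 - pf.gamma - pf.lapse)
    return float(pf.alpha * (-np.log1p(-q)) ** (1.0 / pf.beta))


def alpha_for_threshold(
    threshold: float, criterion: float = THRESHOLD_CRITERION, beta: float = 3.5,
    gamma: float = 0.5, lapse: float = 0.02,
) -> float:
    """Weibull alpha whose ``criterion``-correct contrast equals ``threshold``."""
    q = (criterion - gamma) / (1.0 - gamma - lapse)
    return float(threshold / (-np.log1p(-q)) ** (1.0 / beta))


def alpha_grid(n: int = GRID_SIZE) -> np.ndarray:
    """Log-spaced candidate thresholds for the running fit."""
    return np.logspace(np.log10(CONTRAST_MIN), np.log10(ALPHA_MAX), n)


@dataclass
class StaircaseState:
    """Running-fit state of one adaptive track.

    The grid holds candidate alpha values; ``log_likelihood[i]`` accumulates
    the Bernoulli log likelihood of all observed trials under alpha=grid[i]
    with slope/guess/lapse fixed at their seeds.  With no trials yet the
    estimate is the condition's initial contrast seed.
    """

    initial_contrast: float
    beta: float = 3.5
    gamma: float = 0.5
    lapse: float = 0.02
    grid: np.ndarray = field(default_factory=alpha_grid)
    log_likelihood: np.ndarray | None = None
    trial_history: list[tuple[float, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.log_likelihood is None:
            self.log_likelihood = np.zeros_like(self.grid)

    @property
    def current_estimate(self) -> float:
        """ML alpha estimate; ties break toward lower contrast."""
        if not self.trial_history:
            return float(np.clip(self.initial_contrast, CONTRAST_MIN, CONTRAST_MAX))
        return float(self.grid[int(np.argmax(self.log_likelihood))])


def staircase_update(state: StaircaseState, contrast: float, correct: bool) -> StaircaseState:
    """Fold one trial outcome into the running fit (in place; returns state)."""
    p = state.gamma + (1.0 - state.gamma - state.lapse) * (
        1.0 - np.exp(-((contrast / state.grid) ** state.beta))
    )
    state.log_likelihood += np.log(p) if correct else np.log1p(-p)
    state.trial_history.append((float(contrast), bool(correct)))
    return state


def next_contrast(state: StaircaseState) -> float:
    """Contrast for the next trial: current estimate clamped to the range."""
    return float(np.clip(state.current_estimate, CONTRAST_MIN, CONTRAST_MAX))


def initial_contrast(condition: Condition) -> float:
    """Starting contrast seed: 0.665 for hard far-periphery cells, else 0.475.

    The high seed applies when eccentricity >= 10.5, spacing >= 2.36 and
    wiggle >= 15 (cells expected to need high contrast).
    """
    c = condition
    if c.eccentricity_deg >= 10.5 and c.spacing_deg >= 2.36 and c.wiggle_deg >= 15:
        return 0.665
    return 0.475


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    condition: Condition
    block: int
    trial_index: int
    polarity: int
    side: Side
    contrast: float
    response_side: Side
    correct: bool
    is_warmup: bool
    stimulus_seed: int

    def __post_init__(self) -> None:
        assert self.correct == (self.response_side == self.side)


class Responder(Protocol):
    """Anything that produces a left/right answer given a trial."""

    def respond(
        self, condition: Condition, contrast: float, side: Side, rng: np.random.Generator
    ) -> Side: ...


def run_block(
    participant_id: str,
    condition: Condition,
    observer: Responder,
    n_staircase_trials: int = 80,
    n_warmup: int = 2,
    rng: np.random.Generator | None = None,
    block: int = 0,
) -> tuple[list[TrialRecord], dict[int, StaircaseState]]:
    """Run one block: warm-up trials plus two interleaved staircases.

    The two staircases track positive and negative Gabor polarity and
    alternate strictly.  Warm-up trials (one per polarity) are shown at the
    block's starting contrast and recorded, but never fed to a staircase.
    Stimulus side is a fair coin each trial.
    """
    if rng is None:
        rng = np.random.default_rng()
    start = initial_contrast(condition)
    states = {+1: StaircaseState(start), -1: StaircaseState(start)}
    records: list[TrialRecord] = []

    def one_trial(idx: int, polarity: int, contrast: float, warmup: bool) -> None:
        side: Side = "left" if rng.random() < 0.5 else "right"
        seed = int(rng.integers(0, 2**31 - 1))
        response = observer.respond(condition, contrast, side, rng)
        records.append(
            TrialRecord(
                participant_id=participant_id,
                condition=condition,
                block=block,
                trial_index=idx,
                polarity=polarity,
                side=side,
                contrast=float(contrast),
                response_side=response,
                correct=response == side,
                is_warmup=warmup,
                stimulus_seed=seed,
            )
        )
        if not warmup:
            staircase_update(states[polarity], contrast, response == side)

    idx = 0
    for k in range(n_warmup):
        one_trial(idx, +1 if k % 2 == 0 else -1, start, warmup=True)
        idx += 1
    for k in range(n_staircase_trials):
        polarity = +1 if k % 2 == 0 else -1
        one_trial(idx, polarity, next_contrast(states[polarity]), warmup=False)
        idx += 1
    return records, states


def run_experiment(
    cohort: Iterable,
    conditions: Iterable[Condition],
    rng: np.random.Generator | int | None = None,
    n_staircase_trials: int = 80,
    n_warmup: int = 2,
) -> pd.DataFrame:
    """Run every participant x condition block; return the full trial table.

    ``cohort`` items must expose ``participant_id`` and satisfy the
    ``Responder`` protocol.  Each block gets its own child RNG stream so the
    table is reproducible from the master seed alone.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    conditions = list(conditions)
    rows = []
    for observer in cohort:
        for cond in conditions:
            block_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            records, _ = run_block(
                observer.participant_id,
                cond,
                observer,
                n_staircase_trials=n_staircase_trials,
                n_warmup=n_warmup,
                rng=block_rng,
            )
            for r in records:
                rows.append(
                    {
                        "participant_id": r.participant_id,
                        "eccentricity": cond.eccentricity_deg,
                        "spacing": cond.spacing_deg,
                        "wiggle": cond.wiggle_deg,
                        "block": r.block,
                        "trial_index": r.trial_index,
                        "polarity": r.polarity,
                        "side": r.side,
                        "contrast": r.contrast,
                        "response": r.response_side,
                        "correct": r.correct,
                        "is_warmup": r.is_warmup,
                        "seed": r.stimulus_seed,
                    }
                )
    return pd.DataFrame(rows)
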