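"""Shared fixtures: simulated observers, trial tables, threshold tables.

Heavy simulations are session-scoped so several tests can share one run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from snakegrass.geometry import Condition
from snakegrass.observers import GroundTruthModel, generate_cohort
from snakegrass.pipeline import RunConfig, expand_design
from snakegrass.staircase import (
    WeibullPF,
    alpha_for_threshold,
    pf_eval,
    run_block,
    run_experiment,
)
from snakegrass.thresholds import estimate_thresholds

warnings.filterwarnings("ignore", module="statsmodels")


class WeibullObserver:
    """Stateless responder with a fixed psychometric function."""

    participant_id = "SIM"

    def __init__(self, pf: WeibullPF):
        self.pf = pf

    def respond(self, condition, contrast, side, rng):
        if rng.random() < pf_eval(self.pf, contrast):
            return side
        return "right" if side == "left" else "left"


@pytest.fixture(scope="session")
def known_pf() -> WeibullPF:
    """Observer whose 81%-correct contrast is exactly 0.3."""
    return WeibullPF(alpha=alpha_for_threshold(0.3))


@pytest.fixture(scope="session")
def mid_condition() -> Condition:
    return Condition(10.5, 1.58, 15)


def run_pooled_staircase(pf: WeibullPF, condition: Condition, n_blocks: int, seed: int):
    """Simulate n_blocks x (80+2) trials; return pooled non-warm-up arrays."""
    obs = WeibullObserver(pf)
    rng = np.random.default_rng(seed)
    contrasts, correct = [], []
    for b in range(n_blocks):
        records, _ = run_block("SIM", condition, obs, rng=rng, block=b)
        for r in records:
            if not r.is_warmup:
                contrasts.append(r.contrast)
                correct.append(r.correct)
    return np.array(contrasts), np.array(correct)


def simulate_threshold_table(
    model: GroundTruthModel,
    n_participants: int,
    resid_sd: float,
    seed: int,
    conditions=None,
) -> pd.DataFrame:
    """Directly measured thresholds: logit-linear model plus noise, no
    staircase, no ceiling censoring.  Used to exercise the inference layer
    under a known generative process."""
    rng = np.random.default_rng(seed)
    if conditions is None:
        conditions = expand_design(RunConfig())
    u = rng.normal(0.0, model.participant_sd, size=n_participants)
    rows = []
    for p in range(n_participants):
        for cond in conditions:
            eta = model.logit_threshold(cond) + u[p] + rng.normal(0.0, resid_sd)
            rows.append(
                {
                    "participant_id": f"P{p:02d}",
                    "eccentricity": cond.eccentricity_deg,
                    "spacing": cond.spacing_deg,
                    "wiggle": cond.wiggle_deg,
                    "threshold": 1.0 / (1.0 + np.exp(-eta)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_model() -> GroundTruthModel:
    return GroundTruthModel.default()


@pytest.fixture(scope="session")
def default_trials(default_model) -> pd.DataFrame:
    """Full 12-participant x 45-condition simulated experiment."""
    cohort = generate_cohort(default_model, 12, seed=11)
    return run_experiment(cohort, expand_design(RunConfig()), rng=11)


@pytest.fixture(scope="session")
def default_estimates(default_trials) -> pd.DataFrame:
    """Thresholds + bootstrap SEs for the default experiment."""
    return estimate_thresholds(default_trials, B=250, rng=12)
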