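"""End-to-end orchestration: config, design expansion, run manifest, figures.

A run proceeds simulate -> refit -> filter -> infer -> plot, with every
stage drawing its randomness from a child stream of one master seed, so the
whole output directory is reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Condition
from .lmm import (
    TWO_WAY_TERMS,
    anova_table,
    contrasts_to_frame,
    emmeans_pairwise,
    fit_lmem,
    omega_squared,
    power_simulation,
    stepwise_reduce,
)
from .observers import ECCENTRICITIES, SPACINGS, WIGGLES, GroundTruthModel, generate_cohort
from .staircase import run_experiment
from .thresholds import estimate_thresholds, filter_reliable


@dataclass
class RunConfig:
    """Everything needed to reproduce one full simulated experiment."""

    eccentricities: list[float] = field(default_factory=lambda: list(ECCENTRICITIES))
    spacings: list[float] = field(default_factory=lambda: list(SPACINGS))
    wiggles: list[float] = field(default_factory=lambda: list(WIGGLES))
    n_participants: int = 12
    participant_sd: float = 0.35
    n_staircase_trials: int = 80
    n_warmup: int = 2
    bootstrap_B: int = 250
    alpha: float = 0.05
    power_n_sim: int = 100
    power_shrink: float = 0.85
    master_seed: int = 0
    output_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def expand_design(config: RunConfig) -> list[Condition]:
    """Full factorial condition list in eccentricity-major order."""
    if not (config.eccentricities and config.spacings and config.wiggles):
        raise ValueError("every factor needs at least one level")
    return [
        Condition(e, s, w)
        for e in config.eccentricities
        for s in config.spacings
        for w in config.wiggles
    ]


def _child_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage substream seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def make_figures(
    thresholds: pd.DataFrame, reliability: pd.DataFrame, out_dir: Path
) -> list[str]:
    """Threshold-vs-spacing panels per eccentricity and the reliability map."""
    paths = []
    eccs = sorted(thresholds["eccentricity"].unique())
    wigs = sorted(thresholds["wiggle"].unique())
    colors = plt.cm.viridis(np.linspace(0.1, 0.85, len(wigs)))

    fig, axes = plt.subplots(1, len(eccs), figsize=(4 * len(eccs), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, ecc in zip(axes, eccs):
        sub = thresholds[thresholds["eccentricity"] == ecc]
        for color, wig in zip(colors, wigs):
            cell = sub[sub["wiggle"] == wig]
            mean = cell.groupby("spacing")["threshold"].mean()
            ax.plot(mean.index, mean.values, "o-", color=color, label=f"wiggle {wig:g}°")
            for _, g in cell.groupby("participant_id"):
                g = g.sort_values("spacing")
                ax.plot(g["spacing"], g["threshold"], color=color, alpha=0.15, lw=0.7)
        ax.set_xscale("log")
        ax.set_title(f"eccentricity {ecc:g}°")
        ax.set_xlabel("spacing (deg)")
    axes[0].set_ylabel("contrast threshold")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    p = out_dir / "thresholds_by_spacing.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(str(p))

    fig, axes = plt.subplots(1, len(eccs), figsize=(4 * len(eccs), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, ecc in zip(axes, eccs):
        sub = reliability[reliability["eccentricity"] == ecc]
        for color, wig in zip(colors, wigs):
            cell = sub[sub["wiggle"] == wig].sort_values("spacing")
            ax.plot(cell["spacing"], cell["proportion_reliable"], "o-", color=color,
                    label=f"wiggle {wig:g}°")
        ax.set_xscale("log")
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(f"eccentricity {ecc:g}°")
        ax.set_xlabel("spacing (deg)")
    axes[0].set_ylabel("proportion reliable thresholds")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    p = out_dir / "reliability_by_spacing.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(str(p))
    return paths


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; return (and write) the run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "version": __version__,
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    # simulate
    model = GroundTruthModel.default(participant_sd=config.participant_sd)
    cohort = generate_cohort(model, config.n_participants, seed=_child_seed(config.master_seed, "cohort"))
    conditions = expand_design(config)
    trials = run_experiment(
        cohort, conditions,
        rng=_child_seed(config.master_seed, "trials"),
        n_staircase_trials=config.n_staircase_trials,
        n_warmup=config.n_warmup,
    )
    trials_path = out_dir / "trials.csv"
    trials.to_csv(trials_path, index=False)
    record("trials", trials_path)

    # refit + filter
    estimates = estimate_thresholds(
        trials, B=config.bootstrap_B, rng=_child_seed(config.master_seed, "bootstrap")
    )
    est_path = out_dir / "thresholds.csv"
    estimates.to_csv(est_path, index=False)
    record("thresholds", est_path)
    kept, reliability = filter_reliable(estimates)
    rel_path = out_dir / "reliability.csv"
    reliability.to_csv(rel_path, index=False)
    record("reliability", rel_path)

    # infer
    final, reduction_log = stepwise_reduce(kept, alpha=config.alpha)
    pd.DataFrame(reduction_log).to_csv(out_dir / "model_reduction.csv", index=False)
    record("model_reduction", out_dir / "model_reduction.csv")
    anova = anova_table(final)
    anova.to_csv(out_dir / "anova.csv", index=False)
    record("anova", out_dir / "anova.csv")
    omega = omega_squared(final)

    contrast_paths = {}
    for effect, by in (("spacing", "eccentricity"), ("spacing", "wiggle"), ("wiggle", "eccentricity")):
        try:
            tbl = contrasts_to_frame(emmeans_pairwise(final, effect, by=by))
        except ValueError:
            continue
        p = out_dir / f"contrasts_{effect}_by_{by}.csv"
        tbl.to_csv(p, index=False)
        contrast_paths[f"contrasts_{effect}_by_{by}"] = str(p)
    manifest["outputs"].update(contrast_paths)

    power = power_simulation(
        final,
        terms=[t for t in TWO_WAY_TERMS if t in final.terms],
        shrink=config.power_shrink,
        n_sim=config.power_n_sim,
        alpha=config.alpha,
        rng=_child_seed(config.master_seed, "power"),
    )
    power_df = pd.DataFrame([p.__dict__ for p in power])
    power_df.to_csv(out_dir / "power.csv", index=False)
    record("power", out_dir / "power.csv")

    for p in make_figures(kept, reliability, out_dir):
        record(Path(p).stem, Path(p))

    manifest["final_model_terms"] = list(final.terms)
    manifest["omega_squared"] = omega
    manifest["n_reliable"] = int(len(kept))
    manifest["n_estimates"] = int(len(estimates))
    manifest["runtime_s"] = round(time.time() - t0, 1)
    manifest["outputs"] = {k: str(v) for k, v in manifest["outputs"].items()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
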