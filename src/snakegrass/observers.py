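"""Simulated participants for the snake-detection task.

Each observer answers the 2AFC trial through a Weibull psychometric function
whose 81%-correct contrast (the "true threshold") follows a logit-linear
ground-truth model over the 3 x 5 x 3 design: fixed effects of eccentricity,
spacing and wiggle, all two-way interactions, plus a Gaussian random
intercept per participant.  The default coefficients qualitatively mimic the
empirical pattern of the paradigm: a near-flat spacing effect in the
parafovea (7 deg), steep threshold growth with spacing in the periphery
(10.5 / 15.75 deg), the strongest wiggle effect at 10.5 deg, and ceiling
cells in the far periphery where the true threshold exceeds the displayable
contrast range.

Also provided is a small stimulus-driven "linking" observer that groups
layout elements by proximity and collinearity within an association field
scaled to eccentricity, and answers with the hemifield of the longest chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import expit, logit

from .geometry import Condition, Side, StimulusLayout
from .staircase import WeibullPF, alpha_for_threshold, pf_eval

ECCENTRICITIES = (7.0, 10.5, 15.75)
SPACINGS = (0.70, 1.05, 1.58, 2.36, 3.54)
WIGGLES = (5.0, 15.0, 25.0)


def _decompose_cell_table(logit_cells: np.ndarray) -> dict:
    """ANOVA-style decomposition of a full 3x5x3 logit-threshold array into
    grand mean, sum-to-zero main effects and two-way interactions (any
    three-way remainder is discarded)."""
    m = logit_cells.mean()
    a = logit_cells.mean(axis=(1, 2)) - m  # ecc
    b = logit_cells.mean(axis=(0, 2)) - m  # spacing
    c = logit_cells.mean(axis=(0, 1)) - m  # wiggle
    ab = logit_cells.mean(axis=2) - m - a[:, None] - b[None, :]
    ac = logit_cells.mean(axis=1) - m - a[:, None] - c[None, :]
    bc = logit_cells.mean(axis=0) - m - b[:, None] - c[None, :]
    return {"intercept": float(m), "ecc": a, "spacing": b, "wiggle": c,
            "ecc_spacing": ab, "ecc_wiggle": ac, "spacing_wiggle": bc}


@dataclass
class GroundTruthModel:
    """Logit-scale generative model of true 81%-correct thresholds.

    ``logit(threshold) = intercept + ecc[i] + spacing[j] + wiggle[k]
    + ecc_spacing[i,j] + ecc_wiggle[i,k] + spacing_wiggle[j,k]
    + random_intercept`` with sum-to-zero coded effect arrays indexed by the
    design level order.  Inverse-logit of the linear predictor may exceed
    the 0.95 contrast maximum: those are ceiling cells.
    """

    intercept: float
    ecc: np.ndarray
    spacing: np.ndarray
    wiggle: np.ndarray
    ecc_spacing: np.ndarray
    ecc_wiggle: np.ndarray
    spacing_wiggle: np.ndarray
    participant_sd: float = 0.35
    observer_slope: float = 3.5
    observer_lapse: float = 0.02
    eccentricities: tuple = ECCENTRICITIES
    spacings: tuple = SPACINGS
    wiggles: tuple = WIGGLES

    @classmethod
    def default(cls, participant_sd: float = 0.35) -> "GroundTruthModel":
        """Default coefficients reproducing the paradigm's qualitative pattern."""
        # Mean logit thresholds at the middle wiggle level, by (ecc, spacing):
        # parafovea flat around 0.17; periphery rises steeply with spacing.
        base = logit(np.array([
            [0.12, 0.17, 0.17, 0.175, 0.18],
            [0.15, 0.22, 0.38, 0.65, 0.75],
            [0.28, 0.30, 0.55, 0.93, 0.96],
        ]))
        # Additive wiggle offsets (logit units) per eccentricity; the wiggle
        # effect is steepest at 10.5 deg.
        wiggle_off = np.array([
            [-0.15, 0.0, 0.50],
            [-0.60, 0.0, 0.90],
            [-0.50, 0.0, 0.80],
        ])
        # Mild spacing-by-wiggle modulation: wiggle hurts more at wide spacing.
        s_rank = np.arange(5) - 2.0
        w_rank = np.arange(3) - 1.0
        sw = 0.08 * np.outer(s_rank, w_rank)
        cells = base[:, :, None] + wiggle_off[:, None, :] + sw[None, :, :]
        parts = _decompose_cell_table(cells)
        return cls(participant_sd=participant_sd, **parts)

    def _indices(self, condition: Condition) -> tuple[int, int, int]:
        try:
            i = self.eccentricities.index(condition.eccentricity_deg)
            j = self.spacings.index(condition.spacing_deg)
            k = self.wiggles.index(condition.wiggle_deg)
        except ValueError as err:
            raise KeyError(f"condition {condition} not in the design") from err
        return i, j, k

    def logit_threshold(self, condition: Condition) -> float:
        i, j, k = self._indices(condition)
        return float(
            self.intercept + self.ecc[i] + self.spacing[j] + self.wiggle[k]
            + self.ecc_spacing[i, j] + self.ecc_wiggle[i, k] + self.spacing_wiggle[j, k]
        )


@dataclass
class ObserverParams:
    """One simulated participant: a random intercept on the logit scale."""

    participant_id: str
    random_intercept: float
    model: GroundTruthModel = field(repr=False, default=None)

    def respond(
        self, condition: Condition, contrast: float, side: Side, rng: np.random.Generator
    ) -> Side:
        return simulate_response(self, condition, contrast, side, rng)


def true_threshold(model: GroundTruthModel, observer: ObserverParams | None, condition: Condition) -> float:
    """Observer's true 81%-correct contrast for a condition (may exceed 0.95)."""
    eta = model.logit_threshold(condition)
    if observer is not None:
        eta += observer.random_intercept
    return float(expit(eta))


def observer_pf(model: GroundTruthModel, observer: ObserverParams, condition: Condition) -> WeibullPF:
    """The Weibull function governing this observer's trial responses."""
    thr = true_threshold(model, observer, condition)
    alpha = alpha_for_threshold(
        thr, beta=model.observer_slope, lapse=model.observer_lapse
    )
    return WeibullPF(alpha=alpha, beta=model.observer_slope, lapse=model.observer_lapse)


def simulate_response(
    observer: ObserverParams,
    condition: Condition,
    contrast: float,
    side: Side,
    rng: np.random.Generator,
) -> Side:
    """One Bernoulli trial: correct with the Weibull probability, else the
    other side is reported."""
    pf = observer_pf(observer.model, observer, condition)
    p = pf_eval(pf, contrast)
    if rng.random() < p:
        return side
    return "right" if side == "left" else "left"


def generate_cohort(
    model: GroundTruthModel, n_participants: int = 12, seed: int | None = None
) -> list[ObserverParams]:
    """Draw a reproducible cohort with i.i.d. Normal(0, sd) random intercepts."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, model.participant_sd, size=n_participants)
    return [
        ObserverParams(participant_id=f"P{i + 1:02d}", random_intercept=float(u), model=model)
        for i, u in enumerate(intercepts)
    ]


def _alignment_deviation(ori_a: float, ori_b: float, axis_deg: float) -> float:
    """RMS angular deviation (deg) of two element orientations from the
    axis joining them; 0 for perfectly collinear pairs."""

    def angdiff(a: float, b: float) -> float:
        d = (a - b) % 180.0
        return min(d, 180.0 - d)

    da, db = angdiff(ori_a, axis_deg), angdiff(ori_b, axis_deg)
    return float(np.sqrt(0.5 * (da**2 + db**2)))


def link_elements(
    layout: StimulusLayout,
    field_scale: float = 0.5,
    max_links: int = 2,
    orientation_tolerance_deg: float = 20.0,
    neighbor_k: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy association-field linking over all layout elements.

    Candidate links join an element to its ``neighbor_k`` nearest neighbours
    (only the most proximal elements compete for linking) that lie within
    the association-field radius ``field_scale x eccentricity`` and whose
    deviation from collinearity (between the elements' orientations and
    their joining axis) is within ``orientation_tolerance_deg`` — linking
    is absent beyond the field radius and for strongly misaligned pairs.
    Among candidates, link strength is the product of a distance kernel
    ``exp(-d / (field_scale E))`` and an alignment kernel
    ``exp(-(dev / tol)^2)``; links are accepted strongest first, subject to
    at most ``max_links`` per element and no cycles.

    Returns ``(component_id, degree)`` per element; elements sharing a
    component id belong to one linked chain.
    """
    pts = layout.positions()
    oris = np.array([e.orientation_deg for e in layout.elements])
    radius = field_scale * layout.condition.eccentricity_deg
    degree = np.zeros(len(pts), dtype=int)
    parent = np.arange(len(pts))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = cKDTree(pts)
    k = min(neighbor_k + 1, len(pts))
    dists, nbrs = tree.query(pts, k=k)
    pair_set = set()
    for i in range(len(pts)):
        for d, j in zip(dists[i][1:], nbrs[i][1:]):
            if d <= radius:
                pair_set.add((min(i, int(j)), max(i, int(j))))
    candidates = []
    for i, j in sorted(pair_set):
        vec = pts[j] - pts[i]
        d = float(np.hypot(*vec))
        axis = float(np.rad2deg(np.arctan2(vec[1], vec[0])))
        dev = _alignment_deviation(oris[i], oris[j], axis)
        if dev <= orientation_tolerance_deg:
            candidates.append((i, j, d, dev))
    if candidates:
        pairs = [(i, j) for i, j, _, _ in candidates]
        strengths = [
            np.exp(-d / radius) * np.exp(-((dev / orientation_tolerance_deg) ** 2))
            for _, _, d, dev in candidates
        ]
        for k in np.argsort(strengths)[::-1]:
            i, j = pairs[k]
            if degree[i] >= max_links or degree[j] >= max_links:
                continue
            ri, rj = find(i), find(j)
            if ri == rj:
                continue  # would close a cycle, not lengthen a chain
            parent[ri] = rj
            degree[i] += 1
            degree[j] += 1
    components = np.array([find(i) for i in range(len(pts))])
    return components, degree


def linking_observer_choose_side(
    layout: StimulusLayout,
    field_scale: float = 0.5,
    max_links: int = 2,
    orientation_tolerance_deg: float = 20.0,
    rng: np.random.Generator | None = None,
) -> Side:
    """Answer left/right from the layout alone via association-field linking.

    Runs :func:`link_elements` and reports the hemifield holding the longest
    linked chain, breaking ties (including a chain exactly on the vertical
    meridian) at random.
    """
    if rng is None:
        rng = np.random.default_rng()
    pts = layout.positions()
    components, _ = link_elements(
        layout, field_scale=field_scale, max_links=max_links,
        orientation_tolerance_deg=orientation_tolerance_deg,
    )
    counts = np.bincount(components)
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    root = candidates[rng.integers(len(candidates))] if len(candidates) > 1 else candidates[0]
    mean_x = pts[components == root, 0].mean()
    if mean_x == 0:
        return "left" if rng.random() < 0.5 else "right"
    return "left" if mean_x < 0 else "right"
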