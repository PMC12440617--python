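"""Snake-in-the-grass stimulus geometry.

A stimulus is a field of oriented Gabor elements.  Seven *snake* elements lie
on an imaginary spine of fixed-length segments (*vertebrae*) whose heading
change between neighbours ("wiggle") alternates in sign.  The spine is bent
onto a circle of radius equal to the target eccentricity so that every snake
element sits at the same retinal eccentricity; the remaining vertebrae carry
randomly oriented *ring* elements that close the circle around fixation.
*Grass* (background) elements fill the rest of the display on an approximately
uniform mesh whose pitch equals the mean snake inter-element distance, so that
neither proximity nor local density distinguishes snake from background.

All coordinates are in degrees of visual angle, fixation-centred, x rightward
and y upward.  Orientations are grating-stripe directions in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

#: Hard non-overlap limit: the visible diameter of one Gabor element (4 sigma
#: with sigma = 0.16 deg).  No two element centres may come closer than this.
MIN_ELEMENT_SEPARATION = 0.64

Side = Literal["left", "right"]
Role = Literal["snake", "ring", "grass"]


@dataclass(frozen=True)
class Condition:
    """One cell of the eccentricity x spacing x wiggle design.

    Parameters
    ----------
    eccentricity_deg:
        Radial distance of the element circle from fixation.
    spacing_deg:
        Centre-to-centre distance between neighbouring contour elements
        (vertebra length).
    wiggle_deg:
        Nominal absolute orientation change between neighbouring vertebrae.
    """

    eccentricity_deg: float
    spacing_deg: float
    wiggle_deg: float

    def __post_init__(self) -> None:
        if self.eccentricity_deg <= 0 or self.spacing_deg <= 0:
            raise ValueError("eccentricity and spacing must be positive")
        if self.wiggle_deg < 0:
            raise ValueError("wiggle must be non-negative")


@dataclass(frozen=True)
class ElementSpec:
    """Position, orientation and role of a single Gabor element."""

    x_deg: float
    y_deg: float
    orientation_deg: float
    role: Role

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation_deg", self.orientation_deg % 180.0)
        if self.role not in ("snake", "ring", "grass"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class SnakeSpine:
    """Straight-ish polyline of equal-length vertebrae before circle mapping.

    ``midpoints`` are vertebra centres in local 2D coordinates, ``headings``
    the vertebra directions in degrees.  ``snake_slice`` marks which seven
    consecutive vertebrae carry the snake.
    """

    midpoints: np.ndarray  # (n, 2)
    headings: np.ndarray  # (n,)
    spacing_deg: float
    snake_slice: slice

    @property
    def n_vertebrae(self) -> int:
        return len(self.headings)

    @property
    def snake_indices(self) -> np.ndarray:
        return np.arange(self.snake_slice.start, self.snake_slice.stop)


@dataclass
class StimulusLayout:
    """Complete element layout of one trial."""

    condition: Condition
    side: Side
    elements: list[ElementSpec]
    grass_pitch_deg: float
    rng_seed: int
    #: Max |radius - eccentricity| over snake/ring elements, inherited from
    #: the residuals of the line fit used in circle remapping.
    radial_tolerance_deg: float = 0.0

    def by_role(self, role: Role) -> list[ElementSpec]:
        return [e for e in self.elements if e.role == role]

    def positions(self, role: Role | None = None) -> np.ndarray:
        els = self.elements if role is None else self.by_role(role)
        return np.array([(e.x_deg, e.y_deg) for e in els]).reshape(-1, 2)


def build_spine(
    condition: Condition,
    n_snake: int = 7,
    rng: np.random.Generator | None = None,
    wiggle_jitter_deg: float = 5.0,
) -> SnakeSpine:
    """Construct the vertebra polyline for one stimulus.

    The total vertebra count matches the circumference of the eccentricity
    circle, ``round(2 pi E / s)``, so that after remapping the spine closes
    the circle.  Headings zigzag around the spine axis: vertebra k points at
    ``+/- wiggle/2`` (alternating, first sign random) plus an independent
    jitter uniform in ``+/- wiggle_jitter_deg / 2``.  Consecutive heading
    changes therefore alternate in sign with magnitude within
    ``wiggle +/- wiggle_jitter_deg``, while the heading never accumulates a
    drift — keeping the spine globally straight so that, after circle
    remapping, every snake element stays close to the nominal eccentricity.
    ``wiggle_jitter_deg=0`` together with ``wiggle_deg=0`` yields a
    perfectly straight spine (useful for testing).
    """
    if rng is None:
        rng = np.random.default_rng()
    E, s, w = condition.eccentricity_deg, condition.spacing_deg, condition.wiggle_deg
    n_total = int(round(2.0 * np.pi * E / s))
    if n_total < n_snake + 1:
        raise ValueError(
            f"spacing {s} too large: only {n_total} vertebrae fit on a circle "
            f"of radius {E} (need at least {n_snake + 1})"
        )
    first_sign = 1.0 if rng.random() < 0.5 else -1.0
    signs = first_sign * (-1.0) ** np.arange(n_total)
    jitter = (
        rng.uniform(-wiggle_jitter_deg / 2.0, wiggle_jitter_deg / 2.0, size=n_total)
        if wiggle_jitter_deg > 0
        else np.zeros(n_total)
    )
    headings = signs * (w / 2.0) + jitter

    # Chain vertebrae: each is a segment of length s along its heading.
    rad = np.deg2rad(headings)
    steps = s * np.column_stack([np.cos(rad), np.sin(rad)])
    ends = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    midpoints = 0.5 * (ends[:-1] + ends[1:])

    start = (n_total - n_snake) // 2
    return SnakeSpine(
        midpoints=midpoints,
        headings=headings,
        spacing_deg=s,
        snake_slice=slice(start, start + n_snake),
    )


def _fit_line(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal-axis (orthogonal least squares) line through ``points``.

    Returns (centroid, direction angle in degrees).  The spine starts along
    +x, so the principal axis is oriented to keep a positive x component.
    """
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    direction = vt[0]
    if direction[0] < 0:
        direction = -direction
    return centroid, float(np.rad2deg(np.arctan2(direction[1], direction[0])))


def map_spine_to_circle(
    spine: SnakeSpine,
    condition: Condition,
    side: Side,
    rng: np.random.Generator | None = None,
) -> tuple[list[ElementSpec], float]:
    """Bend the spine onto the eccentricity circle.

    A regression line is fitted to the vertebra midpoints.  The along-line
    coordinate ``t`` of each vertebra becomes arc length on the circle
    (polar angle ``t / E``); the signed perpendicular deviation becomes a
    radial offset, so line-fit residuals turn into small eccentricity errors.
    The central snake vertebra lands at azimuth 180 deg (left) or 0 deg
    (right).  Snake element orientations keep their heading relative to the
    fitted line, rotated by the local polar angle (the angular correction
    that makes the globally straight path circular without touching local
    wiggle statistics); ring vertebrae get uniform random orientations.

    Returns the element list and the maximum |radius - E| over all elements.
    """
    if rng is None:
        rng = np.random.default_rng()
    E = condition.eccentricity_deg
    centroid, line_angle = _fit_line(spine.midpoints)
    rad = np.deg2rad(line_angle)
    u = np.array([np.cos(rad), np.sin(rad)])  # along-line unit vector
    v = np.array([-np.sin(rad), np.cos(rad)])  # perpendicular
    rel = spine.midpoints - centroid
    t = rel @ u
    d = rel @ v

    centre_idx = spine.snake_slice.start + (spine.snake_slice.stop - spine.snake_slice.start) // 2
    az0 = 180.0 if side == "left" else 0.0
    phi = (t - t[centre_idx]) / E  # radians
    azimuth = np.deg2rad(az0) + phi
    radius = E + d

    xs = radius * np.cos(azimuth)
    ys = radius * np.sin(azimuth)
    # Along-line direction maps to the circle tangent: an element at azimuth
    # a is oriented a + 90 deg plus its heading deviation from the fitted line.
    local_heading = spine.headings - line_angle
    snake_orient = np.rad2deg(azimuth) + 90.0 + local_heading

    elements: list[ElementSpec] = []
    snake_set = set(range(spine.snake_slice.start, spine.snake_slice.stop))
    for i in range(spine.n_vertebrae):
        if i in snake_set:
            ori = snake_orient[i]
            role: Role = "snake"
        else:
            ori = rng.uniform(0.0, 180.0)
            role = "ring"
        elements.append(ElementSpec(float(xs[i]), float(ys[i]), float(ori), role))
    tolerance = float(np.max(np.abs(radius - E)))
    return elements, tolerance


def _hex_grid(h: float, halfwidth: float, halfheight: float, rng: np.random.Generator) -> np.ndarray:
    """Hexagonal candidate grid with pitch h covering the screen rectangle."""
    dy = h * np.sqrt(3.0) / 2.0
    ys = np.arange(-halfheight, halfheight + dy, dy)
    pts = []
    for j, y in enumerate(ys):
        offset = 0.0 if j % 2 == 0 else h / 2.0
        xs = np.arange(-halfwidth + offset, halfwidth + h, h)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    grid = np.vstack(pts)
    # small jitter breaks the degenerate collinearity of a perfect lattice
    grid = grid + rng.uniform(-0.05 * h, 0.05 * h, size=grid.shape)
    keep = (np.abs(grid[:, 0]) <= halfwidth) & (np.abs(grid[:, 1]) <= halfheight)
    return grid[keep]


def _relax_mesh(
    free: np.ndarray,
    fixed: np.ndarray,
    h: float,
    project,
    n_iter: int = 50,
    move_tol: float = 0.01,
) -> np.ndarray:
    """Distmesh-style force relaxation toward uniform edge length h.

    Delaunay edges act as compressed springs (repulsive only); ``fixed``
    points never move; ``project`` clamps free points back into the region.
    Stops after ``n_iter`` sweeps or when the largest move < ``move_tol*h``.
    """
    if len(free) == 0:
        return free
    for _ in range(n_iter):
        pts = np.vstack([fixed, free]) if len(fixed) else free
        if len(pts) < 4:
            break
        tri = Delaunay(pts)
        edges = np.unique(
            np.sort(
                np.vstack([tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]], tri.simplices[:, [0, 2]]]),
                axis=1,
            ),
            axis=0,
        )
        vec = pts[edges[:, 1]] - pts[edges[:, 0]]
        length = np.linalg.norm(vec, axis=1)
        length[length == 0] = 1e-9
        # distmesh uses slightly over-long rest length so points spread out
        rest = 1.2 * h
        fmag = np.maximum(rest - length, 0.0)
        fvec = (fmag / length)[:, None] * vec
        force = np.zeros_like(pts)
        np.add.at(force, edges[:, 0], -fvec)
        np.add.at(force, edges[:, 1], fvec)
        step = 0.2 * force[len(fixed):]
        new_free = project(free + step)
        move = np.max(np.linalg.norm(new_free - free, axis=1))
        free = new_free
        if move < move_tol * h:
            break
    return free


def mesh_grass(
    fixed_elements: Sequence[ElementSpec],
    condition: Condition,
    screen_halfwidth_deg: float,
    screen_halfheight_deg: float,
    rng: np.random.Generator | None = None,
) -> list[ElementSpec]:
    """Fill the display with grass elements on a near-uniform mesh.

    The target pitch ``h`` is the mean centre-to-centre distance between
    consecutive snake elements.  Two passes of iterative Delaunay relaxation
    place points first inside the element circle, then in the annulus between
    the circle and the screen rectangle, with the snake/ring positions held
    fixed as mesh anchors.  Grass closer than ``MIN_ELEMENT_SEPARATION`` to
    any element is rejected.  Grass orientations are uniform random.
    """
    if rng is None:
        rng = np.random.default_rng()
    E = condition.eccentricity_deg
    if E + MIN_ELEMENT_SEPARATION / 2 > max(screen_halfwidth_deg, screen_halfheight_deg):
        raise ValueError("screen too small to contain the element circle")

    snake = [e for e in fixed_elements if e.role == "snake"]
    spts = np.array([(e.x_deg, e.y_deg) for e in snake])
    h = float(np.mean(np.linalg.norm(np.diff(spts, axis=0), axis=1))) if len(spts) > 1 else condition.spacing_deg

    fixed_pts = np.array([(e.x_deg, e.y_deg) for e in fixed_elements]).reshape(-1, 2)
    hw, hh = screen_halfwidth_deg, screen_halfheight_deg

    def in_rect(p: np.ndarray) -> np.ndarray:
        return (np.abs(p[:, 0]) <= hw) & (np.abs(p[:, 1]) <= hh)

    grid = _hex_grid(h, hw, hh, rng)
    r_grid = np.linalg.norm(grid, axis=1)
    tree = cKDTree(fixed_pts)

    def far_from_fixed(p: np.ndarray, cut: float) -> np.ndarray:
        return tree.query(p)[0] > cut

    def clamp_rect(p: np.ndarray) -> np.ndarray:
        return np.column_stack([np.clip(p[:, 0], -hw, hw), np.clip(p[:, 1], -hh, hh)])

    grass_pts: list[np.ndarray] = []

    # Pass 1: interior of the element circle (leave a guard ring near the
    # fixed circle so interior points do not crowd the contour).
    inner_r = E - 0.8 * h
    seed_in = grid[(r_grid < inner_r) & far_from_fixed(grid, 0.8 * h)]

    def project_inner(p: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(p, axis=1)
        over = r > inner_r
        p = p.copy()
        if np.any(over):
            p[over] *= (inner_r / r[over])[:, None]
        return clamp_rect(p)

    relaxed_in = _relax_mesh(seed_in, fixed_pts, h, project_inner)
    if len(relaxed_in):
        grass_pts.append(relaxed_in)

    # Pass 2: annulus from the circle out to the screen edges.
    outer_r = E + 0.8 * h
    seed_out = grid[(r_grid > outer_r) & in_rect(grid) & far_from_fixed(grid, 0.8 * h)]

    def project_outer(p: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(p, axis=1)
        under = r < outer_r
        p = p.copy()
        if np.any(under):
            r_safe = np.where(r[under] == 0, 1e-9, r[under])
            p[under] *= (outer_r / r_safe)[:, None]
        return clamp_rect(p)

    anchors = np.vstack([fixed_pts, relaxed_in]) if len(relaxed_in) else fixed_pts
    relaxed_out = _relax_mesh(seed_out, anchors, h, project_outer)
    if len(relaxed_out):
        grass_pts.append(relaxed_out)

    if not grass_pts:
        return []
    pts = np.vstack(grass_pts)

    # Reject grass violating the hard separation limit, nearest-to-fixed and
    # then pairwise (greedy removal of the worse-offending point).
    sep = max(MIN_ELEMENT_SEPARATION, 0.0)
    pts = pts[tree.query(pts)[0] > sep]
    keep = np.ones(len(pts), dtype=bool)
    gtree = cKDTree(pts)
    for i, j in sorted(gtree.query_pairs(sep)):
        if keep[i] and keep[j]:
            keep[j] = False
    pts = pts[keep]

    return [
        ElementSpec(float(x), float(y), float(rng.uniform(0.0, 180.0)), "grass")
        for x, y in pts
    ]


def apply_peripheral_jitter(
    grass: Sequence[ElementSpec],
    condition: Condition,
    h: float,
    rng: np.random.Generator | None = None,
    jitter_fraction: float = 0.05,
) -> list[ElementSpec]:
    """Jitter grass elements far from the eccentricity circle.

    Elements whose radial distance differs from the target eccentricity by
    more than ``3 h`` receive an independent per-axis offset uniform in
    ``+/- jitter_fraction * h``; all others are returned unchanged.  This
    breaks up the overly regular appearance of the far mesh without touching
    the neighbourhood of the contour.
    """
    if rng is None:
        rng = np.random.default_rng()
    E = condition.eccentricity_deg
    out: list[ElementSpec] = []
    for e in grass:
        r = np.hypot(e.x_deg, e.y_deg)
        if abs(r - E) > 3.0 * h:
            dx, dy = rng.uniform(-jitter_fraction * h, jitter_fraction * h, size=2)
            out.append(replace(e, x_deg=e.x_deg + float(dx), y_deg=e.y_deg + float(dy)))
        else:
            out.append(e)
    return out


def build_stimulus(
    condition: Condition,
    side: Side,
    rng_seed: int,
    screen_halfwidth_deg: float = 26.6,
    screen_halfheight_deg: float = 15.0,
    n_snake: int = 7,
) -> StimulusLayout:
    """Build the full deterministic element layout for one trial.

    Composes spine construction, circle remapping, grass meshing and
    peripheral jitter; identical seeds give identical layouts.  Ring
    elements falling outside the screen rectangle are dropped (the snake is
    centred on the horizontal meridian and always fits).
    """
    rng = np.random.default_rng(rng_seed)
    spine = build_spine(condition, n_snake=n_snake, rng=rng)
    circle_elements, tolerance = map_spine_to_circle(spine, condition, side, rng=rng)
    hw, hh = screen_halfwidth_deg, screen_halfheight_deg
    circle_elements = [
        e
        for e in circle_elements
        if e.role == "snake" or (abs(e.x_deg) <= hw and abs(e.y_deg) <= hh)
    ]
    grass = mesh_grass(circle_elements, condition, hw, hh, rng=rng)
    snake_pts = np.array([(e.x_deg, e.y_deg) for e in circle_elements if e.role == "snake"])
    h = float(np.mean(np.linalg.norm(np.diff(snake_pts, axis=0), axis=1)))
    jittered = apply_peripheral_jitter(grass, condition, h, rng=rng)

    # Revert any jitter that pushed a point inside the hard separation limit
    # (iterate: a revert can only move a point back to its conflict-free
    # mesh position, so this terminates).
    fixed_pts = np.array([(e.x_deg, e.y_deg) for e in circle_elements])
    orig_pts = np.array([(g.x_deg, g.y_deg) for g in grass]).reshape(-1, 2)
    cur = np.array([(g.x_deg, g.y_deg) for g in jittered]).reshape(-1, 2)
    for _ in range(5):
        if len(cur) == 0:
            break
        allpts = np.vstack([fixed_pts, cur])
        tree = cKDTree(allpts)
        dist, _ = tree.query(np.vstack([fixed_pts, cur]), k=2)
        nearest = dist[len(fixed_pts):, 1]
        bad = nearest <= MIN_ELEMENT_SEPARATION
        if not np.any(bad):
            break
        cur[bad] = orig_pts[bad]
    final_grass = [
        replace(g, x_deg=float(x), y_deg=float(y))
        for g, (x, y) in zip(jittered, cur)
    ]

    return StimulusLayout(
        condition=condition,
        side=side,
        elements=list(circle_elements) + final_grass,
        grass_pitch_deg=h,
        rng_seed=rng_seed,
        radial_tolerance_deg=tolerance,
    )
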