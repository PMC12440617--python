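# Methods

This note documents the models, algorithms and design choices behind
`snakegrass`, in the order data flows through the pipeline: stimulus
geometry → rendering → adaptive procedure → synthetic observers →
threshold re-estimation → mixed-effects inference. It also states what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Stimulus geometry (`snakegrass.geometry`)

**Spine.** A stimulus begins as a polyline of `round(2πE/s)` equal-length
segments ("vertebrae") of length *s* (the inter-element spacing), enough to
close a circle of radius *E* (the eccentricity). Seven consecutive central
vertebrae carry the snake; the rest become the randomly oriented ring.
Vertebra headings zigzag around the spine axis: vertebra *k* points at
±w/2 (alternating, first sign random per stimulus) plus independent
uniform jitter of ±2.5°. Consecutive heading changes therefore alternate
in sign with magnitude in [w − 5°, w + 5°] (triangular within that band),
and — crucially — the heading never accumulates a random-walk drift. A
cumulative-increment construction with the same per-step statistics bows
long spines by ~√n and would scatter snake elements up to ~1° in
eccentricity; the zigzag keeps the spine globally straight so that all
snake elements end up near the nominal eccentricity, which is what makes
thresholds comparable across spacings (performance is otherwise dominated
by the farthest element).

**Circle remapping.** An orthogonal least-squares line is fitted to the
vertebra midpoints. Each midpoint's along-line coordinate *t* maps to polar
angle t/E (the snake centre pinned to azimuth 180° for "left", 0° for
"right"); its signed perpendicular deviation maps to a radial offset, so
line-fit residuals become small eccentricity errors whose maximum is
recorded on the layout (`radial_tolerance_deg`, typically ≲ 0.1°). Snake
element orientations keep their heading relative to the fitted line and
rotate with the local polar angle (tangent + deviation); ring orientations
are uniform in [0°, 180°). Because elements sit at vertebra midpoints,
centre-to-centre distance is s·cos(Δ/2) for heading change Δ — within 2%
of *s* for wiggles up to 15°, ≈ 2.4% short at 25°. The per-layout mean
snake distance is recorded and used as the grass pitch.

**Grass meshing.** Grass is distributed by iterative Delaunay relaxation
(distmesh-style): hexagonal seeding at pitch *h* (= mean snake centre
distance), then up to 50 sweeps in which Delaunay edges act as repulsive
springs with rest length 1.2 h and step 0.2, stopping when the largest
move is < 0.01 h. Two passes fill (1) the interior of the element circle
and (2) the annulus from the circle to the screen rectangle, with
snake/ring positions held fixed as anchors and a guard band of 0.8 h
around them. No two elements may come closer than 0.64° (the visible
Gabor diameter); offending grass points are rejected. Grass farther than
3 h from the target eccentricity receives ±5%-of-pitch uniform positional
jitter per axis (jitter that would violate the 0.64° limit is reverted).
The result carries no proximity cue: mean snake-to-nearest-grass distance
matches mean grass-to-grass distance within 15%.

**Screen.** Geometry is degrees-native; the default virtual screen is
±26.6° × ±15.0°. The element circle at the largest eccentricity does not
fit vertically; ring and grass are clipped to the screen, which loses no
task information because the snake is centred on the horizontal meridian.
An error is raised only if the circle cannot fit in the wider screen
dimension.

## Rendering (`snakegrass.render`)

Elements are cosine-phase (centre-symmetric) Gabors: carrier frequency
2.5 cyc/deg, circular Gaussian envelope σ = 0.16°, drawn additively on a
0.5 mid-grey background and clipped to [0, 1]. Polarity flips the carrier
sign; all simultaneously rendered elements share one contrast and
polarity. The envelope is truncated at 3σ for rasterisation; the *visible*
extent is conventionally quoted at the e⁻² level (2σ radius), giving a
4σ = 0.64° diameter. Output is a float array, exportable as 8-bit PNG;
display linearisation and high-bit-depth pipelines are out of scope.

## Adaptive procedure (`snakegrass.staircase`)

The task is spatial 2AFC (γ = 0.5). The running fit tracks only the
Weibull threshold α on a 151-point log-spaced grid, with slope (3.5),
guess and lapse (0.02) fixed at their seeds; each trial adds its Bernoulli
log-likelihood to every grid point, and the estimate is the grid argmax
(ties to the lower contrast). The next trial is presented at the estimate
clamped to the displayable range [0.001, 0.95].

The α grid spans [0.001, 4.0] — beyond the displayable maximum — at the
same log density as a 121-point grid over [0.001, 0.95]. This matters for
failing cells: an observer who underperforms the criterion even at full
contrast has its maximum-likelihood α far above 0.95, and a grid capped at
the display maximum would pin every bootstrap resample to the cap,
silently collapsing the standard error exactly where it must be large.

Blocks hold 80 staircase trials split strictly alternately between two
interleaved staircases (one per Gabor polarity), preceded by 2 warm-up
trials (one per polarity) at the starting contrast that are recorded but
never enter a staircase. The starting contrast is 0.475, or 0.665 in the
hard far-periphery cells (E ≥ 10.5°, s ≥ 2.36°, w ≥ 15°). Stimulus side
is a fair coin per trial. Thresholds are read out by analytic inversion
of the Weibull at 81% correct.

## Synthetic observers (`snakegrass.observers`)

True 81%-correct thresholds follow a logit-linear model over the 3 × 5 × 3
design: intercept, sum-to-zero main effects of eccentricity, spacing and
wiggle, all two-way interactions (no three-way), plus a Normal(0, 0.35²)
random intercept per participant on the logit scale. The default cell
means encode the paradigm's qualitative phenomenology: thresholds ~0.12 at
the closest parafoveal spacing and near-flat (~0.17–0.18) across the rest
of the 7° row; steep growth with spacing at 10.5° and 15.75°; the wiggle
effect steepest at 10.5°; and far-periphery × high-wiggle cells above the
0.95 display maximum (ceiling cells). These values are the package's own
choices for a realistic synthetic cohort, not fitted values from any
dataset.

An observer answers a trial correctly with probability given by its
Weibull function (α derived from the cell's true threshold by inverting
the 81% criterion; β = 3.5, λ = 0.02 by default, both configurable);
otherwise it reports the opposite side.

A stimulus-driven **linking observer** is also provided as a documented
reconstruction of an association-field account: candidate links join an
element to its 6 nearest neighbours within a field radius of 0.5 E, only
if both orientations are within 20° (RMS) of collinear with the joining
axis; links are accepted greedily by strength (distance kernel
exp(−d/0.5E) × alignment kernel exp(−(dev/20°)²)) with at most 2 links
per element and no cycles; the response is the hemifield of the longest
chain. The nearest-neighbour restriction keeps accidental grass linking
below the percolation threshold; without it, spurious chains outgrow any
7-element snake in a dense display. It is a qualitative mechanism probe,
not a fitted model.

## Threshold re-estimation (`snakegrass.thresholds`)

All non-warm-up trials of a participant × condition cell (both polarities
pooled) are replayed through a running fit identical to the online one;
because the fit sums independent per-trial log-likelihoods, the estimate
is order-invariant, and the nonparametric case-resampling bootstrap
(B = 250) reduces to one matrix product per cell. The reported threshold
is clipped to the displayable [0.001, 0.95] (keeping the logit defined
downstream); the bootstrap SE is the standard deviation of the
*unclipped* resample thresholds, on the contrast scale — 0.2 is only
interpretable as a bound on that scale. Estimates with SE > 0.2 are
flagged unreliable and excluded (SE = 0.2 exactly is kept); the per-cell
proportion of reliable estimates is reported alongside.

## Inference (`snakegrass.lmm`)

Reliable thresholds are logit-transformed and fitted with `statsmodels`
MixedLM: categorical fixed effects (sum-to-zero contrasts) and a
participant random intercept. Backward reduction starts from the full
factorial model under ML, repeatedly testing the removable (highest-order)
terms by chi-square difference tests and dropping the least harmful term
while its p > 0.05; the final model is refit by REML. Term-wise tests are
marginal Wald F statistics with numerator df from the term's columns and
denominator df = N − rank(X) (a deliberate approximation; no
Satterthwaite/Kenward–Roger correction). Ω² is defined here as the
proportional reduction in residual variance relative to an intercept-only
model with the same random structure. Estimated marginal means average
model predictions over the factors not involved; all pairwise differences
within a family are Tukey-adjusted via the studentized range with the
residual df. Contrasts are reported as (lower level − higher level), so
negative values mean the response increases along the factor.

Power is estimated by simulation from the fitted model: fixed effects
(except the intercept) multiplied by 0.85 — a 15% shrink guarding against
selection-inflated effect sizes — variance components preserved; each
simulated dataset is refit and each term of interest tested by LRT at
α = 0.05. Removing a term also removes retained higher-order terms
containing it: in a factorial design the higher-order term re-spans a
dropped marginal subspace, which would otherwise make the comparison
vacuous (0 df). When no higher-order term is retained (the intended,
paper-like case) this is the plain single-term LRT.

## What the generator does and does not emulate

The synthetic cohort reproduces: per-trial Bernoulli 2AFC responses with
guesses and lapses; between-participant threshold variability; the
factorial threshold structure with pairwise interactions; and ceiling
behaviour in far-periphery/high-wiggle cells, which yields elevated
bootstrap SEs and a falling proportion of reliable thresholds there.

It does **not** emulate: learning or fatigue across blocks; polarity- or
session-dependent performance; eye movements and fixation breaks; crowding
anisotropies; or genuinely at-chance observers. The last point is a
structural property worth knowing: with true thresholds bounded inside
(0, 1) by the inverse logit and slope 3.5, an observer's accuracy at the
0.95 contrast maximum never falls below ≈ 0.78, so simulated staircases
degrade but never fail outright, and per-cell unreliability saturates
around 20–25% rather than the near-total convergence failure real
observers can show. Passing tests therefore demonstrate that the pipeline
*detects* ceiling-induced unreliability and that its inferential machinery
is calibrated — not that the generator spans the full range of human
failure modes.

Two measurement artifacts are intentional and documented rather than
hidden. First, clipping re-fit thresholds at 0.95 in ceiling cells bends
the measured logit surface and manufactures a small three-way interaction
that the generator does not contain; on default (ceiling-laden) cohorts
the reduction may therefore retain the three-way term. Calibration
properties of the reduction are accordingly evaluated on uncensored
cohorts. Second, the plain ML chi-square difference test for the 16-df
three-way term is anticonservative at 12 participants (~10% type-I rate).
This is a small-sample property of the test itself, not of the
implementation — the log-likelihoods and χ² agree with lme4 to numerical
precision (a cross-check test pins this) — and the rate is nominal at 40
participants, where the calibration test is run; the Wald-F tests are
nominal at 12.

## Problem sizes and numerical choices

Defaults: 12 participants × 45 conditions × (80 + 2) trials; 151-point α
grid over [0.001, 4.0]; bootstrap B = 250; mesh relaxation ≤ 50 sweeps,
tolerance 0.01 h; power simulations n = 100. Test-suite simulations use
reduced sizes chosen for statistical sufficiency (e.g. 100 replicate
160-trial staircases for criterion targeting; 200 replicate cohorts for
type-I calibration; 50-participant cohorts for parameter recovery).
Likelihood ties break toward the lower contrast (conservative placement);
MixedLM uses its default optimizer cascade (a single L-BFGS pass can stop
on a singular random-effects boundary for this design); all randomness
flows through explicitly seeded NumPy generators, with per-stage child
seeds derived from one master seed by hashing.
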