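"""Mixed-effects inference on logit-transformed contrast thresholds.

Reliable thresholds are logit-transformed and modelled as a linear mixed
model: categorical fixed effects of eccentricity (3 levels), wiggle (3) and
spacing (5) with interactions up to third order, and a random intercept per
participant.  Model reduction proceeds backwards from the full factorial
model under ML, removing terms whose exclusion does not worsen fit by a
chi-square (likelihood-ratio) difference test; the final model is refit by
REML.  Term-wise tests, an omega-squared effect size, estimated marginal
means with Tukey-adjusted pairwise contrasts, and simulation-based power
(with fixed effects shrunk by 15% to correct for selection-induced
overestimation) are derived from the fit.

Factors use sum-to-zero contrasts so the term-wise Wald tests are marginal
(type-III-like).  Denominator degrees of freedom use the residual
``N - rank(X)`` approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.special import logit
from statsmodels.regression.mixed_linear_model import MixedLM

FACTORS = ("eccentricity", "wiggle", "spacing")
FULL_TERMS = (
    "eccentricity", "wiggle", "spacing",
    "eccentricity:wiggle", "eccentricity:spacing", "wiggle:spacing",
    "eccentricity:wiggle:spacing",
)
TWO_WAY_TERMS = ("eccentricity:wiggle", "eccentricity:spacing", "wiggle:spacing")
DEFAULT_ALPHA = 0.05


def _formula_rhs(terms: tuple[str, ...] | list[str]) -> str:
    parts = []
    for term in terms:
        factors = term.split(":")
        parts.append(":".join(f"C({f}, Sum)" for f in factors))
    return " + ".join(parts) if parts else "1"


def _term_label(patsy_term) -> str | None:
    """Map a patsy term back to its 'eccentricity:spacing'-style label."""
    names = []
    for factor in patsy_term.factors:
        for f in FACTORS:
            if f in factor.name():
                names.append(f)
                break
    if not names:
        return None  # intercept
    return ":".join(sorted(names, key=FACTORS.index))


@dataclass
class LMEMFit:
    """A fitted mixed model plus everything needed for derived tables."""

    result: object  # statsmodels MixedLMResults
    terms: tuple[str, ...]
    method: str  # "ML" | "REML"
    design_info: object
    exog: np.ndarray
    groups: np.ndarray
    y: np.ndarray
    data: pd.DataFrame = field(repr=False)

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def n_fixed(self) -> int:
        return self.exog.shape[1]

    @property
    def fe_params(self) -> np.ndarray:
        return np.asarray(self.result.fe_params)

    @property
    def fe_cov(self) -> np.ndarray:
        return np.asarray(self.result.cov_params())[: self.n_fixed, : self.n_fixed]

    @property
    def residual_var(self) -> float:
        return float(self.result.scale)

    @property
    def participant_var(self) -> float:
        return float(np.asarray(self.result.cov_re)[0, 0])

    @property
    def ddf(self) -> int:
        """Residual denominator df: N minus fixed-effect rank."""
        return int(len(self.y) - np.linalg.matrix_rank(self.exog))

    def term_slices(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for patsy_term, sl in self.design_info.term_slices.items():
            label = _term_label(patsy_term)
            if label is not None:
                out[label] = np.arange(sl.start, sl.stop)
        return out


def fit_lmem(
    thresholds: pd.DataFrame,
    terms: tuple[str, ...] | list[str] = FULL_TERMS,
    method: str = "ML",
) -> LMEMFit:
    """Fit logit(threshold) on the given fixed terms with participant
    random intercepts.

    ``thresholds`` needs columns participant_id, eccentricity, spacing,
    wiggle and threshold; thresholds must lie strictly inside (0, 1).
    """
    if thresholds["participant_id"].nunique() < 2:
        raise ValueError("mixed model needs at least two participants")
    thr = thresholds["threshold"].to_numpy(dtype=float)
    if np.any(thr <= 0) or np.any(thr >= 1):
        raise ValueError("thresholds must be strictly inside (0, 1) before logit")
    data = thresholds.copy()
    data["logit_threshold"] = logit(thr)
    X = patsy.dmatrix(_formula_rhs(terms), data, return_type="dataframe")
    groups = data["participant_id"].to_numpy()
    y = data["logit_threshold"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X.to_numpy(), groups)
        result = model.fit(reml=(method == "REML"))
    return LMEMFit(
        result=result,
        terms=tuple(terms),
        method=method,
        design_info=X.design_info,
        exog=X.to_numpy(),
        groups=groups,
        y=y,
        data=data,
    )


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float
    drop: bool  # True when the tested term(s) can be removed


def lrt_reduce(full: LMEMFit, reduced: LMEMFit, alpha: float = DEFAULT_ALPHA) -> LRTResult:
    """Chi-square difference test between nested ML fits.

    ``drop`` is True when the reduced model is not significantly worse, i.e.
    the extra terms may be removed.
    """
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("likelihood-ratio tests require ML fits")
    df = full.n_fixed - reduced.n_fixed
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=float(chi2), df=int(df), p_value=p, drop=(df == 0) or (p > alpha))


def _removable(terms: tuple[str, ...]) -> list[str]:
    """Terms not contained in any retained higher-order term (hierarchy)."""
    out = []
    for t in terms:
        fs = set(t.split(":"))
        if not any(fs < set(o.split(":")) for o in terms):
            out.append(t)
    return out


def stepwise_reduce(
    thresholds: pd.DataFrame,
    start_terms: tuple[str, ...] = FULL_TERMS,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[LMEMFit, list[dict]]:
    """Backward model reduction by chi-square difference tests under ML.

    Highest-order removable terms are tested one at a time (least harmful
    first) and removed while removal does not significantly worsen fit.
    Returns the final model refit by REML and a log of every test.
    """
    terms = tuple(start_terms)
    current = fit_lmem(thresholds, terms, method="ML")
    log: list[dict] = []
    while terms:
        candidates = sorted(_removable(terms), key=lambda t: -len(t.split(":")))
        best_term: str | None = None
        best_p = -np.inf
        best_fit: LMEMFit | None = None
        tests: dict[str, dict] = {}
        for t in candidates:
            reduced = fit_lmem(thresholds, tuple(x for x in terms if x != t), method="ML")
            res = lrt_reduce(current, reduced, alpha=alpha)
            tests[t] = {"dropped": t, "chi2": res.chi2, "df": res.df,
                        "p_value": res.p_value, "removed": False}
            if res.drop and res.p_value > best_p:
                best_term, best_p, best_fit = t, res.p_value, reduced
        log.extend(tests.values())
        if best_term is None:
            break
        tests[best_term]["removed"] = True
        terms = best_fit.terms
        current = best_fit
    final = fit_lmem(thresholds, terms, method="REML")
    return final, log


def anova_table(fit: LMEMFit) -> pd.DataFrame:
    """Marginal (drop-one) Wald F tests for every fixed term.

    Numerator df equal the term's column count; denominator df use the
    residual N - rank approximation.
    """
    cov = fit.fe_cov
    beta = fit.fe_params
    ddf = fit.ddf
    rows = []
    for term, idx in fit.term_slices().items():
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        q = len(idx)
        F = float(b @ np.linalg.solve(V, b)) / q
        p = float(stats.f.sf(F, q, ddf))
        rows.append({"term": term, "F": F, "df_num": q, "df_den": ddf, "p_value": p})
    order = {t: i for i, t in enumerate(FULL_TERMS)}
    rows.sort(key=lambda r: order.get(r["term"], 99))
    return pd.DataFrame(rows)


def omega_squared(fit: LMEMFit, null_fit: LMEMFit | None = None) -> float:
    """Effect size: proportional reduction in residual variance relative to
    an intercept-only model with the same random structure."""
    if null_fit is None:
        null_fit = fit_lmem(fit.data, terms=(), method=fit.method)
    return float(1.0 - fit.residual_var / null_fit.residual_var)


def _emm_vectors(fit: LMEMFit, effect: str, by: str | None) -> pd.DataFrame:
    """Design-row averages defining each estimated marginal mean."""
    levels = {f: sorted(fit.data[f].unique()) for f in FACTORS}
    grid = pd.MultiIndex.from_product(
        [levels[f] for f in FACTORS], names=FACTORS
    ).to_frame(index=False)
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)
    keys = [effect] + ([by] if by else [])
    rows = []
    for vals, g in grid.groupby(keys, sort=True):
        if not isinstance(vals, tuple):
            vals = (vals,)
        L = X[g.index.to_numpy()].mean(axis=0)
        rows.append({**dict(zip(keys, vals)), "L": L})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastResult:
    effect: str
    by: str | None
    by_level: object
    level_a: object
    level_b: object
    estimate: float
    se: float
    t_value: float
    p_adjusted: float


def emmeans_pairwise(
    fit: LMEMFit, effect: str, by: str | None = None
) -> list[ContrastResult]:
    """All pairwise differences of estimated marginal means of ``effect``,
    within each level of ``by``, Tukey-adjusted within each family.

    Marginal means average model predictions over the factors not named;
    the Tukey adjustment uses the studentized range with residual df.
    Estimates are ``emm(level_a) - emm(level_b)`` with a < b in level order,
    so a contrast is negative when the response increases along the factor.
    """
    if not any(effect in t.split(":") for t in fit.terms):
        raise ValueError(f"effect {effect!r} not in the model")
    emms = _emm_vectors(fit, effect, by)
    beta, cov, ddf = fit.fe_params, fit.fe_cov, fit.ddf
    k = fit.data[effect].nunique()
    out: list[ContrastResult] = []
    by_levels = sorted(emms[by].unique()) if by else [None]
    for bl in by_levels:
        fam = emms if bl is None else emms.loc[emms[by] == bl]
        fam = fam.sort_values(effect).reset_index(drop=True)
        for i, j in combinations(range(len(fam)), 2):
            L = fam.loc[i, "L"] - fam.loc[j, "L"]
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, ddf))
            out.append(
                ContrastResult(
                    effect=effect, by=by, by_level=bl,
                    level_a=fam.loc[i, effect], level_b=fam.loc[j, effect],
                    estimate=est, se=se, t_value=float(t), p_adjusted=min(1.0, p),
                )
            )
    return out


def contrasts_to_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])


@dataclass(frozen=True)
class PowerResult:
    term: str
    power_percent: float
    se_percent: float
    n_simulations: int
    shrink: float


def simulate_from_fit(fit: LMEMFit, shrink: float, rng: np.random.Generator) -> np.ndarray:
    """One response vector from the fitted model with shrunken fixed effects.

    Fixed effects are multiplied by ``shrink`` (intercept included in the
    linear predictor but not shrunk); variance components are preserved.
    """
    beta = fit.fe_params.copy()
    beta[1:] *= shrink
    eta = fit.exog @ beta
    sd_u = np.sqrt(fit.participant_var)
    sd_e = np.sqrt(fit.residual_var)
    _, inv = np.unique(fit.groups, return_inverse=True)
    u = rng.normal(0.0, sd_u, size=inv.max() + 1)
    return eta + u[inv] + rng.normal(0.0, sd_e, size=len(eta))


def power_simulation(
    fit: LMEMFit,
    terms: tuple[str, ...] | list[str] = TWO_WAY_TERMS,
    shrink: float = 0.85,
    n_sim: int = 100,
    alpha: float = DEFAULT_ALPHA,
    rng: np.random.Generator | int | None = None,
) -> list[PowerResult]:
    """Simulation-based power for each term of interest.

    Each simulated dataset is drawn from the fitted model with fixed effects
    shrunk by ``shrink`` (default 15% reduction, guarding against
    selection-inflated effect sizes); the full model and the model without
    the term are refit by ML and compared by LRT.  Removing a term also
    removes any retained higher-order term containing it: a factorial
    design re-spans a dropped marginal subspace through its higher-order
    term, which would otherwise make the comparison vacuous (0 df).  Power
    is the percentage of simulations in which the term is significant, with
    its binomial SE.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    terms = [t for t in terms if t in fit.terms]
    hits = {t: 0 for t in terms}
    reduced_terms = {
        t: tuple(
            x for x in fit.terms
            if x != t and not set(t.split(":")) < set(x.split(":"))
        )
        for t in terms
    }
    data = fit.data
    for _ in range(n_sim):
        y = simulate_from_fit(fit, shrink, rng)
        sim_data = data.copy()
        sim_data["threshold"] = 1.0 / (1.0 + np.exp(-y))  # inverse logit
        full = fit_lmem(sim_data, fit.terms, method="ML")
        for t in terms:
            reduced = fit_lmem(sim_data, reduced_terms[t], method="ML")
            res = lrt_reduce(full, reduced, alpha=alpha)
            if res.p_value <= alpha:
                hits[t] += 1
    out = []
    for t in terms:
        p_hat = hits[t] / n_sim
        out.append(
            PowerResult(
                term=t,
                power_percent=100.0 * p_hat,
                se_percent=100.0 * float(np.sqrt(p_hat * (1 - p_hat) / n_sim)),
                n_simulations=n_sim,
                shrink=shrink,
            )
        )
    return out
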