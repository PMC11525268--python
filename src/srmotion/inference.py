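"""Statistical analysis pipeline for the two-block motion experiment.

Block 1 (thresholding) is analysed with an ordinary linear model of
ln(threshold) on scaled age × staircase-numerosity group, with sequential
F-tests, partial eta², and back-transformed marginal means.

Block 2 (constant stimuli) is analysed with binomial random-intercept
mixed models of trial accuracy on orthogonal polynomials of log dot
numerosity (degrees 1–4), scaled age (continuous or dichotomised) and
their interaction.  Candidate degrees are compared by AICc with Akaike
weights; the selected model gets Type III Wald chi-square tests,
Nakagawa's marginal R², semipartial (part) R² per term, population-level
accuracy predictions, peak-location estimates, and a simulation-based
uniformity check of randomized quantile residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .experiment import DOT_LEVELS
from .glmm import GlmmFit, fit_binomial_glmm

__all__ = [
    "zscale",
    "OrthoPoly",
    "orthogonal_poly",
    "DesignSpec",
    "LmFit",
    "fit_threshold_lm",
    "prepare_trials",
    "fit_logistic_glmm",
    "aicc",
    "akaike_weights",
    "model_selection_table",
    "wald_type3",
    "marginal_r2",
    "part_r2",
    "predict_accuracy",
    "PeakEstimate",
    "peak_location",
    "evaluate_quartic",
    "dichotomize_age",
    "simulated_residual_ks",
]


# --------------------------------------------------------------------------
# covariate preparation

def zscale(x) -> tuple[np.ndarray, float, float]:
    """Centre and scale by the sample SD (ddof=1); returns (z, center, spread)."""
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot scale a constant column")
    c = float(x.mean())
    s = float(x.std(ddof=1))
    return (x - c) / s, c, s


class OrthoPoly:
    """Orthogonal polynomial basis via the Forsythe three-term recurrence.

    Columns 1..degree are orthonormal on the fitted x (optionally weighted),
    each with zero (weighted) sum; the recurrence coefficients are stored so
    new x values map into the same basis — the behaviour regression users
    expect from poly()-style contrasts.
    """

    def __init__(self, x, degree: int, weights=None):
        x = np.asarray(x, dtype=float)
        if not 1 <= degree <= 4:
            raise ValueError("degree must be in 1..4")
        if np.unique(x).size <= degree:
            raise ValueError("need more distinct x values than the degree")
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
        self.degree = degree
        self.alpha = np.zeros(degree)
        self.norm2 = np.zeros(degree + 1)  # weighted squared norms, p_0 .. p_degree
        p_prev = np.zeros_like(x)
        p_curr = np.ones_like(x)
        self.norm2[0] = np.sum(w * p_curr**2)
        for j in range(degree):
            self.alpha[j] = np.sum(w * x * p_curr**2) / np.sum(w * p_curr**2)
            p_next = (x - self.alpha[j]) * p_curr
            if j > 0:
                p_next -= (self.norm2[j] / self.norm2[j - 1]) * p_prev
            p_prev, p_curr = p_curr, p_next
            self.norm2[j + 1] = np.sum(w * p_curr**2)

    def transform(self, x) -> np.ndarray:
        """Evaluate the basis (columns 1..degree, unit-norm scaling) at new x."""
        x = np.asarray(x, dtype=float)
        cols = []
        p_prev = np.zeros_like(x)
        p_curr = np.ones_like(x)
        for j in range(self.degree):
            p_next = (x - self.alpha[j]) * p_curr
            if j > 0:
                p_next -= (self.norm2[j] / self.norm2[j - 1]) * p_prev
            p_prev, p_curr = p_curr, p_next
            cols.append(p_curr / math.sqrt(self.norm2[j + 1]))
        return np.column_stack(cols)


def orthogonal_poly(x, degree: int, weights=None) -> tuple[np.ndarray, OrthoPoly]:
    """Basis matrix plus the fitted recurrence (for prediction-time reuse)."""
    op = OrthoPoly(x, degree, weights)
    return op.transform(np.asarray(x, dtype=float)), op


# --------------------------------------------------------------------------
# block 1: ln-threshold linear model

@dataclass
class LmFit:
    """OLS fit of ln(threshold) with per-term F tests and marginal means."""

    params: pd.Series
    anova: pd.DataFrame  # term, ss, df, F, p, partial_eta2
    emmeans: pd.DataFrame  # group, emm_ln, se, emm_dots
    age_slope_ln: float  # per year of age, on the ln scale
    resid_var: float
    n: int


def fit_threshold_lm(participants: pd.DataFrame) -> LmFit:
    """ln(threshold) ~ scaled age × group (sum-to-zero), sequential F-tests.

    Marginal means per staircase group are evaluated at the mean age and
    back-transformed to the dot/percent scale by exponentiation; the age
    effect is also reported per year of age on the ln scale.
    """
    df = participants
    for col in ("threshold_pct", "age", "group_dots"):
        if col not in df.columns:
            raise ValueError(f"participant table lacks column {col!r}")
    if df.groupby("group_dots").size().min() < 2:
        raise ValueError("need at least 2 participants per group")
    y = np.log(df["threshold_pct"].to_numpy(dtype=float))
    age_z, age_c, age_s = zscale(df["age"])
    g = np.where(df["group_dots"].to_numpy() == 100, 1.0, -1.0)  # sum-to-zero
    X_terms = {
        "group": g[:, None],
        "age": age_z[:, None],
        "age:group": (age_z * g)[:, None],
    }
    ones = np.ones((len(df), 1))

    def rss(cols) -> tuple[float, int]:
        X = np.hstack([ones, *cols])
        fit = sm.OLS(y, X).fit()
        return float(fit.ssr), int(fit.df_resid)

    order = ["group", "age", "age:group"]
    rss_prev, _ = rss([])
    X_full = np.hstack([ones] + [X_terms[t] for t in order])
    full = sm.OLS(y, X_full).fit()
    ss_resid, df_resid = float(full.ssr), int(full.df_resid)
    rows = []
    cols_so_far = []
    for term in order:
        cols_so_far.append(X_terms[term])
        rss_now, _ = rss(cols_so_far)
        ss_term = rss_prev - rss_now
        rss_prev = rss_now
        df_term = X_terms[term].shape[1]
        if ss_resid <= 0:
            F = p = float("nan")
        else:
            F = (ss_term / df_term) / (ss_resid / df_resid)
            p = float(stats.f.sf(F, df_term, df_resid))
        rows.append(
            {
                "term": term,
                "ss": ss_term,
                "df": df_term,
                "F": F,
                "p": p,
                "partial_eta2": ss_term / (ss_term + ss_resid) if ss_term + ss_resid > 0 else 0.0,
            }
        )
    anova = pd.DataFrame(rows)

    # marginal means per group at the mean age (age_z = 0)
    emm_rows = []
    cov = np.asarray(full.cov_params())
    for group, gv in ((100, 1.0), (400, -1.0)):
        xr = np.array([1.0, gv, 0.0, 0.0])
        est = float(xr @ full.params)
        se = float(np.sqrt(xr @ cov @ xr))
        emm_rows.append({"group_dots": group, "emm_ln": est, "se": se, "emm_dots": math.exp(est)})
    names = ["intercept", "group", "age", "age:group"]
    return LmFit(
        params=pd.Series(full.params, index=names),
        anova=anova,
        emmeans=pd.DataFrame(emm_rows),
        age_slope_ln=float(full.params[2]) / age_s,
        resid_var=ss_resid / df_resid if df_resid else float("nan"),
        n=len(df),
    )


# --------------------------------------------------------------------------
# block 2: binomial GLMM

@dataclass(frozen=True)
class DesignSpec:
    """Fixed-effect layout for the accuracy GLMM."""

    degree: int = 4
    age_mode: str = "continuous"  # continuous | group | none
    interaction: bool = True
    response: str = "correct"

    def __post_init__(self) -> None:
        if not 1 <= self.degree <= 4:
            raise ValueError("degree must be 1..4")
        if self.age_mode not in ("continuous", "group", "none"):
            raise ValueError("age_mode must be continuous, group or none")

    @property
    def name(self) -> str:
        return {1: "Linear", 2: "Quadratic", 3: "Cubic", 4: "Fourth degree"}[self.degree]


def prepare_trials(trials: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Aggregate block-2 trials to participant × level binomial counts."""
    need = {"participant_id", "n_dots", "correct"}
    if not need <= set(trials.columns):
        raise ValueError(f"trial table needs columns {sorted(need)}")
    agg = (
        trials.groupby(["participant_id", "n_dots"])["correct"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    agg = agg.merge(participants[["participant_id", "age"]], on="participant_id", how="left")
    if agg["age"].isna().any():
        missing = agg.loc[agg["age"].isna(), "participant_id"].unique()
        raise ValueError(f"ages missing for participants {missing[:5]}")
    return agg


def _build_design(
    agg: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str], dict[str, slice], dict]:
    logn = np.log(agg["n_dots"].to_numpy(dtype=float))
    w = agg["trials"].to_numpy(dtype=float)
    basis, op = orthogonal_poly(logn, design.degree, weights=w)
    cols = [np.ones((len(agg), 1))]
    names = ["intercept"]
    slices: dict[str, slice] = {}
    slices["n_dots"] = slice(1, 1 + design.degree)
    cols.append(basis)
    names += [f"poly{j}" for j in range(1, design.degree + 1)]
    meta: dict = {"poly": op, "degree": design.degree, "age_mode": design.age_mode}
    pos = 1 + design.degree
    if design.age_mode != "none":
        if design.age_mode == "continuous":
            # scale() over trial rows: weight by trial counts
            ages = agg["age"].to_numpy(dtype=float)
            c = float(np.average(ages, weights=w))
            s2 = np.average((ages - c) ** 2, weights=w) * w.sum() / (w.sum() - 1)
            s = float(np.sqrt(s2))
            a = (ages - c) / s
            meta["age_center"], meta["age_spread"] = c, s
        else:
            labels = dichotomize_age(agg["age"].to_numpy(dtype=float))
            a = np.where(labels == "younger", 1.0, -1.0)  # sum-to-zero
        slices["age"] = slice(pos, pos + 1)
        cols.append(a[:, None])
        names.append("age")
        pos += 1
        if design.interaction:
            slices["n_dots:age"] = slice(pos, pos + design.degree)
            cols.append(basis * a[:, None])
            names += [f"poly{j}:age" for j in range(1, design.degree + 1)]
            pos += design.degree
    X = np.hstack(cols)
    return X, names, slices, meta


def fit_logistic_glmm(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    design: DesignSpec,
    nodes: int = 15,
    compute_vcov: bool = True,
) -> GlmmFit:
    """Fit the accuracy GLMM for one candidate design.

    Trials are aggregated to participant × level cells (identical
    covariates), which leaves the Bernoulli likelihood unchanged; the AICc
    sample size is the trial count.
    """
    agg = prepare_trials(trials, participants)
    X, names, slices, meta = _build_design(agg, design)
    fit = fit_binomial_glmm(
        X,
        agg["successes"].to_numpy(dtype=float),
        agg["trials"].to_numpy(dtype=float),
        agg["participant_id"].to_numpy(),
        nodes=nodes,
        term_names=names,
        term_slices=slices,
        compute_vcov=compute_vcov,
    )
    fit.meta.update(meta)
    fit.meta["design"] = design
    fit.meta["X"] = X
    fit.meta["response_checksum"] = float(agg["successes"].sum())
    return fit


# --------------------------------------------------------------------------
# model selection

def aicc(loglik: float, K: int, n_obs: int) -> float:
    """Small-sample corrected Akaike criterion."""
    if n_obs <= K + 1:
        raise ValueError("AICc needs n_obs > K + 1")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n_obs - K - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """Relative model support: exp(-delta/2), normalised after min-shift."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be finite and non-empty")
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def model_selection_table(fits: list[GlmmFit], names: list[str] | None = None) -> pd.DataFrame:
    """AICc comparison table, sorted ascending (best first).

    Columns mirror the conventional layout: Model, K, AICc, Delta_AICc,
    AICcWt, Cum_Wt, LL.  All fits must be on the same data.
    """
    if not fits:
        raise ValueError("no fits")
    n0 = fits[0].n_obs
    ck = fits[0].meta.get("response_checksum")
    for f in fits[1:]:
        if f.n_obs != n0 or f.meta.get("response_checksum") != ck:
            raise ValueError("model selection requires identical data across fits")
    if names is None:
        names = [
            f.meta["design"].name if "design" in f.meta else f"model{i}"
            for i, f in enumerate(fits)
        ]
    rows = pd.DataFrame(
        {
            "Model": names,
            "K": [f.K for f in fits],
            "AICc": [aicc(f.loglik, f.K, f.n_obs) for f in fits],
            "LL": [f.loglik for f in fits],
        }
    ).sort_values("AICc", kind="mergesort", ignore_index=True)
    rows["Delta_AICc"] = rows["AICc"] - rows["AICc"].iloc[0]
    rows["AICcWt"] = akaike_weights(rows["AICc"].to_numpy())
    rows["Cum_Wt"] = rows["AICcWt"].cumsum()
    return rows[["Model", "K", "AICc", "Delta_AICc", "AICcWt", "Cum_Wt", "LL"]]


# --------------------------------------------------------------------------
# tests and effect sizes on the selected model

def wald_type3(fit: GlmmFit) -> pd.DataFrame:
    """Type III Wald chi-square test per term block (sum-to-zero factors)."""
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    rows = []
    for term, sl in fit.term_slices.items():
        b = fit.beta[sl]
        V = fit.vcov[sl, sl]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            raise ValueError(f"singular covariance block for term {term!r}") from None
        df = b.size
        rows.append({"term": term, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows)


def marginal_r2(fit: GlmmFit, X: np.ndarray | None = None) -> float:
    """Nakagawa's marginal R² for logit mixed models.

    Fixed-effect variance over fixed + random-intercept + logistic
    distribution-specific variance (π²/3).
    """
    if X is None:
        X = fit.meta.get("X")
        if X is None:
            raise ValueError("design matrix required")
    lp = X @ fit.beta
    var_f = float(np.var(lp))
    return var_f / (var_f + fit.sigma_u2 + math.pi**2 / 3.0)


def part_r2(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    design: DesignSpec,
    term: str,
    nodes: int = 15,
) -> float:
    """Semipartial ΔR²: drop in marginal R² when ``term`` is removed.

    The reference model is the full model for the interaction term and the
    interaction-free model for main effects (so a main effect is never
    judged in the presence of its own interaction).
    """
    from dataclasses import replace as dc_replace

    if term == "n_dots:age":
        ref = design
        red = dc_replace(design, interaction=False)
    elif term == "age":
        ref = dc_replace(design, interaction=False)
        red = dc_replace(design, interaction=False, age_mode="none")
    elif term == "n_dots":
        ref = dc_replace(design, interaction=False)
        red = None  # reduced model is age-only, built below
    else:
        raise ValueError(f"unknown term {term!r}")
    ref_fit = fit_logistic_glmm(trials, participants, ref, nodes=nodes, compute_vcov=False)
    r2_ref = marginal_r2(ref_fit)
    if term == "n_dots":
        # age-only model
        agg = prepare_trials(trials, participants)
        if design.age_mode == "none":
            return r2_ref
        X_age = _age_only_design(agg, design)
        red_fit = fit_binomial_glmm(
            X_age,
            agg["successes"].to_numpy(float),
            agg["trials"].to_numpy(float),
            agg["participant_id"].to_numpy(),
            nodes=nodes,
            compute_vcov=False,
        )
        r2_red = marginal_r2(red_fit, X_age)
    else:
        red_fit = fit_logistic_glmm(trials, participants, red, nodes=nodes, compute_vcov=False)
        r2_red = marginal_r2(red_fit)
    return r2_ref - r2_red


def _age_only_design(agg: pd.DataFrame, design: DesignSpec) -> np.ndarray:
    ages = agg["age"].to_numpy(dtype=float)
    w = agg["trials"].to_numpy(dtype=float)
    if design.age_mode == "continuous":
        c = float(np.average(ages, weights=w))
        s = float(np.sqrt(np.average((ages - c) ** 2, weights=w) * w.sum() / (w.sum() - 1)))
        a = (ages - c) / s
    else:
        a = np.where(dichotomize_age(ages) == "younger", 1.0, -1.0)
    return np.column_stack([np.ones(len(agg)), a])


# --------------------------------------------------------------------------
# predictions and peaks

def predict_accuracy(fit: GlmmFit, age: float | str | None, n_dots_grid) -> np.ndarray:
    """Population-level predicted accuracy (random intercept at zero).

    ``age`` is a year value for continuous-age fits, a "younger"/"older"
    label for dichotomised fits, or None for age-free fits.  Grid values
    outside the fitted 20–2000 dot range trigger a warning.
    """
    import warnings

    grid = np.asarray(n_dots_grid, dtype=float)
    if grid.min() < min(DOT_LEVELS) or grid.max() > max(DOT_LEVELS):
        warnings.warn("extrapolating outside the fitted 20-2000 dot range", stacklevel=2)
    op: OrthoPoly = fit.meta["poly"]
    basis = op.transform(np.log(grid))
    cols = [np.ones(len(grid)), basis]
    mode = fit.meta.get("age_mode", "none")
    if mode != "none":
        if mode == "continuous":
            a = (float(age) - fit.meta["age_center"]) / fit.meta["age_spread"]
        else:
            a = 1.0 if age == "younger" else -1.0
        cols.append(np.full((len(grid), 1), a))
        if "n_dots:age" in fit.term_slices:
            cols.append(basis * a)
    X = np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])
    return expit(X @ fit.beta)


@dataclass(frozen=True)
class PeakEstimate:
    label: str
    peak_n_dots: float
    peak_log_n: float
    accuracy_at_peak: float


def peak_location(fit: GlmmFit, age: float | str | None, grid_size: int = 2001) -> PeakEstimate:
    """Accuracy-maximising dot numerosity on a dense log-spaced grid.

    Requires a model of degree ≥ 2 (a linear trend has no interior peak);
    ties resolve to the smaller numerosity.
    """
    if fit.meta.get("degree", 0) < 2:
        raise ValueError("peak location needs polynomial degree >= 2")
    grid = np.geomspace(min(DOT_LEVELS), max(DOT_LEVELS), grid_size)
    acc = predict_accuracy(fit, age, grid)
    i = int(np.argmax(acc))
    return PeakEstimate(
        label=str(age),
        peak_n_dots=float(grid[i]),
        peak_log_n=float(np.log(grid[i])),
        accuracy_at_peak=float(acc[i]),
    )


def evaluate_quartic(coeffs, x: float) -> float:
    """c0 + c1 x + c2 x² + c3 x³ + c4 x⁴ for printed prediction equations."""
    c = list(coeffs)
    if len(c) != 5:
        raise ValueError("need exactly 5 coefficients")
    return float(sum(ci * x**i for i, ci in enumerate(c)))


def dichotomize_age(ages, cut: float = 50.0) -> np.ndarray:
    """Split ages into younger (< cut) and older (>= cut) labels."""
    ages = np.asarray(ages, dtype=float)
    return np.where(ages < cut, "younger", "older")


# --------------------------------------------------------------------------
# residual diagnostics

def simulated_residual_ks(
    fit: GlmmFit,
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    n_sim: int = 250,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Simulation-based uniformity check of randomized quantile residuals.

    Simulates ``n_sim`` replicate response vectors from the fitted model
    (fresh random intercepts each time), computes each observation's
    randomized PIT rank among its simulations, and KS-tests the ranks
    against Uniform(0, 1).  Returns (D, p).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    agg = prepare_trials(trials, participants)
    X = fit.meta["X"]
    y = agg["successes"].to_numpy(dtype=int)
    n = agg["trials"].to_numpy(dtype=int)
    pid = agg["participant_id"].to_numpy()
    _, gidx = np.unique(pid, return_inverse=True)
    n_groups = gidx.max() + 1
    eta_fixed = X @ fit.beta
    sims = np.empty((n_sim, len(y)), dtype=int)
    sd_u = math.sqrt(max(fit.sigma_u2, 0.0))
    for s in range(n_sim):
        u = rng.normal(0.0, sd_u, n_groups)
        sims[s] = rng.binomial(n, expit(eta_fixed + u[gidx]))
    less = (sims < y).mean(axis=0)
    equal = (sims == y).mean(axis=0)
    pit = less + rng.random(len(y)) * (equal + 1.0 / n_sim)
    pit = np.clip(pit, 1e-12, 1 - 1e-12)
    res = stats.kstest(pit, "uniform")
    return float(res.statistic), float(res.pvalue)
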