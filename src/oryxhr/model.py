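"""Gaussian additive mixed models for hourly heart rate.

The model is an additive predictor over the hourly analysis table,

    hr_mean ~ intercept + f1(activity) + f2(hour) + season
              + f2s(hour) deviations by season + f3(temperature)
              + animal random intercept,

fitted by penalized least squares with a Gaussian response and identity
link.  Smooth terms are natural cubic regression splines with a fixed
basis dimension equal to the requested degrees of freedom (the
zero-penalty member of the penalized family that hits the target
effective df exactly); each smooth is column-centered so its fitted
values sum to zero over the data (identifiability), and factors use
sum-to-zero (effects) coding.  The per-animal random intercept is a
ridge-penalized set of group indicators whose variance is estimated by
Schall's fixed-point iteration (sigma^2 and tau^2 updated from the
residual sum of squares and the shrunken coefficients until the ridge
weight lambda = sigma^2/tau^2 converges).

Model comparison uses AIC = -2 logLik + 2 edf, where edf is the trace
of the hat matrix (fixed columns plus shrunken random intercepts) and
the log-likelihood is the Gaussian ML value at the fitted residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf
from scipy import linalg, stats

from .errors import FittingError, SingularDesignError

__all__ = [
    "Smooth",
    "Factor",
    "SmoothByFactor",
    "Linear",
    "ModelSpec",
    "FitResult",
    "AcfReport",
    "SubsampleComparison",
    "fit_additive_model",
    "compare_models",
    "residual_acf",
    "subsample_refit",
    "partial_effect_table",
    "standard_ladder",
    "prepare_model_frame",
    "activity_effect_estimate",
    "hour_amplitude_estimate",
    "season_effects_estimate",
]

_LAMBDA_MIN, _LAMBDA_MAX = 1e-8, 1e10


# ---------------------------------------------------------------------------
# Model terms and spec


@dataclass(frozen=True)
class Smooth:
    """Natural cubic regression spline with ``df`` basis functions."""

    var: str
    df: int = 3

    def __post_init__(self):
        if self.df < 2:
            raise FittingError(f"smooth df must be >= 2, got {self.df} for {self.var}")

    @property
    def name(self) -> str:
        return f"s({self.var})"


@dataclass(frozen=True)
class Factor:
    """Categorical term with sum-to-zero (effects) coding."""

    var: str

    @property
    def name(self) -> str:
        return self.var


@dataclass(frozen=True)
class SmoothByFactor:
    """Per-level smooth deviations from a shared smooth of ``var``.

    Deviations sum to zero across factor levels; the shared
    :class:`Smooth` of ``var`` must also be in the spec.
    """

    var: str
    by: str
    df: int = 3

    @property
    def name(self) -> str:
        return f"s({self.var}):{self.by}"


@dataclass(frozen=True)
class Linear:
    """Plain linear term (centered)."""

    var: str

    @property
    def name(self) -> str:
        return self.var


Term = Union[Smooth, Factor, SmoothByFactor, Linear]


@dataclass(frozen=True)
class ModelSpec:
    """An additive model: ordered terms plus an optional random intercept."""

    name: str
    terms: tuple = ()
    random_intercept: Optional[str] = "animal_id"
    response: str = "hr_mean"

    def variables(self) -> list:
        out = [self.response]
        for t in self.terms:
            out.append(t.var)
            if isinstance(t, SmoothByFactor):
                out.append(t.by)
        if self.random_intercept:
            out.append(self.random_intercept)
        return list(dict.fromkeys(out))


# ---------------------------------------------------------------------------
# Basis construction


class _NsBasis:
    """Natural cubic spline basis with knots at quantiles of the data.

    ``df`` columns (truncated-power natural spline basis, constant
    dropped); degrades gracefully to a linear column when the variable
    has too few distinct values.
    """

    def __init__(self, x: np.ndarray, df: int):
        qs = np.linspace(0.0, 1.0, df + 1)
        knots = np.unique(np.quantile(x, qs))
        if len(knots) < 3:
            self.knots = None  # linear fallback
            self.ncol = 1
        else:
            self.knots = knots
            self.ncol = len(knots) - 1
        self.col_means: Optional[np.ndarray] = None

    def _raw(self, x: np.ndarray) -> np.ndarray:
        if self.knots is None:
            return x[:, None].astype(float)
        k = self.knots
        K = len(k)

        def d(j):
            return (np.clip(x - k[j], 0, None) ** 3
                    - np.clip(x - k[-1], 0, None) ** 3) / (k[-1] - k[j])

        cols = [x.astype(float)]
        dlast = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - dlast)
        return np.column_stack(cols)

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        B = self._raw(x)
        self.col_means = B.mean(axis=0)
        return B - self.col_means

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self._raw(np.asarray(x, dtype=float)) - self.col_means


class _EffectsCoding:
    """Sum-to-zero coding: one column per non-reference level."""

    def __init__(self, values: np.ndarray):
        self.levels = sorted(pd.unique(values).tolist())
        if len(self.levels) < 2:
            raise FittingError("factor needs >= 2 observed levels")
        self.ncol = len(self.levels) - 1

    def transform(self, values: np.ndarray) -> np.ndarray:
        vals = np.asarray(values)
        out = np.zeros((len(vals), self.ncol))
        last = self.levels[-1]
        for j, lev in enumerate(self.levels[:-1]):
            out[:, j] = (vals == lev).astype(float) - (vals == last).astype(float)
        return out

    def effect_weights(self) -> np.ndarray:
        """Rows mapping coded coefficients to per-level effects."""
        W = np.vstack([np.eye(self.ncol), -np.ones(self.ncol)])
        return W  # (n_levels, ncol)


class _Design:
    """Fixed-effects design matrix with per-term column bookkeeping."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        n = len(data)
        cols = [np.ones((n, 1))]
        self.slices = {"(Intercept)": slice(0, 1)}
        self.encoders = {}
        start = 1
        for term in spec.terms:
            if isinstance(term, Smooth):
                enc = _NsBasis(data[term.var].to_numpy(dtype=float), term.df)
                B = enc.fit_transform(data[term.var].to_numpy(dtype=float))
            elif isinstance(term, Linear):
                x = data[term.var].to_numpy(dtype=float)
                enc = ("linear", float(x.mean()))
                B = (x - enc[1])[:, None]
            elif isinstance(term, Factor):
                enc = _EffectsCoding(data[term.var].to_numpy())
                B = enc.transform(data[term.var].to_numpy())
            elif isinstance(term, SmoothByFactor):
                basis = _NsBasis(data[term.var].to_numpy(dtype=float), term.df)
                Bv = basis.fit_transform(data[term.var].to_numpy(dtype=float))
                coding = _EffectsCoding(data[term.by].to_numpy())
                E = coding.transform(data[term.by].to_numpy())
                B = np.hstack([Bv * E[:, [j]] for j in range(coding.ncol)])
                enc = (basis, coding)
            else:  # pragma: no cover - spec types are closed
                raise FittingError(f"unknown term type {term!r}")
            self.encoders[term.name] = enc
            cols.append(B)
            self.slices[term.name] = slice(start, start + B.shape[1])
            start += B.shape[1]
        self.X = np.hstack(cols)
        self.p = self.X.shape[1]


# ---------------------------------------------------------------------------
# Fit result containers


@dataclass
class FitResult:
    """A fitted additive mixed model."""

    spec: ModelSpec
    n: int
    coef_table: pd.DataFrame
    log_likelihood: float
    edf: float
    aic: float
    sigma2: float
    tau2: Optional[float]
    r2_generalized: float
    random_effects: Optional[pd.Series]
    frame: pd.DataFrame  # row-aligned: fitted, residual, group/time keys
    dropped_rows: int
    beta: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    design: _Design = field(repr=False, default=None)

    @property
    def residuals(self) -> np.ndarray:
        return self.frame["residual"].to_numpy()

    @property
    def fitted(self) -> np.ndarray:
        return self.frame["fitted"].to_numpy()


@dataclass
class AcfReport:
    """Residual autocorrelation by lag, within-animal and pooled."""

    table: pd.DataFrame  # lag, acf_within, acf_pooled

    def within(self, lag: int) -> float:
        return float(self.table.set_index("lag").loc[lag, "acf_within"])

    def pooled(self, lag: int) -> float:
        return float(self.table.set_index("lag").loc[lag, "acf_pooled"])


@dataclass
class SubsampleComparison:
    """Side-by-side coefficient tables of full vs subsampled fits."""

    comparison: pd.DataFrame
    max_abs_std_diff: float
    full: FitResult
    subsample: FitResult


# ---------------------------------------------------------------------------
# Fitting


def _complete_rows(data: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise FittingError(f"missing covariates in data: {missing}")
    return data.dropna(subset=list(variables))


def fit_additive_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the additive model by penalized least squares.

    Rows with a missing response or covariate are dropped (count
    reported on the result).  Requires >= 50 complete rows and, when a
    random intercept is requested, >= 2 groups.
    """
    used = spec.variables()
    kept = _complete_rows(data, used)
    dropped = len(data) - len(kept)
    if len(kept) < 50:
        raise FittingError(f"need >= 50 complete rows, have {len(kept)}")
    y = kept[spec.response].to_numpy(dtype=float)
    n = len(y)

    design = _Design(kept, spec)
    X = design.X
    p = design.p

    groups = None
    if spec.random_intercept:
        groups = pd.Categorical(kept[spec.random_intercept])
        g = len(groups.categories)
        if g < 2:
            raise FittingError("random intercept requires >= 2 groups")
        Z = np.zeros((n, g))
        Z[np.arange(n), groups.codes] = 1.0
        C = np.hstack([X, Z])
    else:
        g = 0
        C = X

    CtC = C.T @ C
    Cty = C.T @ y
    yty = float(y @ y)

    def solve(lam: float):
        A = CtC.copy()
        if g:
            A[p:, p:] += lam * np.eye(g)
        try:
            cf = linalg.cho_factor(A)
        except linalg.LinAlgError as exc:
            raise SingularDesignError(
                f"design is rank deficient for model '{spec.name}'") from exc
        theta = linalg.cho_solve(cf, Cty)
        Ainv = linalg.cho_solve(cf, np.eye(A.shape[0]))
        M = Ainv @ CtC
        edf_total = float(np.trace(M))
        edf_b = float(np.trace(M[p:, p:])) if g else 0.0
        rss = yty - 2 * theta @ Cty + theta @ (CtC @ theta)
        rss = max(float(rss), 0.0)
        return theta, Ainv, edf_total, edf_b, rss

    lam = 1.0
    tau2 = None
    if g:
        for _ in range(200):  # Schall fixed-point iteration
            theta, Ainv, edf_total, edf_b, rss = solve(lam)
            b = theta[p:]
            sigma2 = rss / max(n - edf_total, 1.0)
            bb = float(b @ b)
            if bb < 1e-12 or edf_b < 1e-8:
                lam_new = _LAMBDA_MAX
            else:
                tau2 = bb / edf_b
                lam_new = np.clip(sigma2 / tau2, _LAMBDA_MIN, _LAMBDA_MAX)
            if abs(np.log(lam_new) - np.log(lam)) < 1e-9:
                lam = lam_new
                break
            lam = lam_new
        theta, Ainv, edf_total, edf_b, rss = solve(lam)
        sigma2 = rss / max(n - edf_total, 1.0)
        bb = float(theta[p:] @ theta[p:])
        tau2 = bb / edf_b if edf_b > 1e-8 else 0.0
    else:
        theta, Ainv, edf_total, edf_b, rss = solve(0.0)
        sigma2 = rss / max(n - edf_total, 1.0)

    fitted = C @ theta
    resid = y - fitted
    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    aic = -2.0 * loglik + 2.0 * edf_total
    cov = sigma2 * Ainv

    # generalized R^2 against the intercept-only Gaussian likelihood
    s2_null = max(float(np.var(y)), 1e-300)
    ll_null = -0.5 * n * (np.log(2 * np.pi * s2_null) + 1.0)
    r2g = 1.0 - np.exp((2.0 / n) * (ll_null - loglik))

    coef = _coef_table(spec, design, theta, cov, n, edf_total)

    re = None
    if g:
        re = pd.Series(theta[p:], index=list(groups.categories), name="random_intercept")

    frame_cols = {}
    for key in ("animal_id", "hour_start"):
        if key in kept.columns:
            frame_cols[key] = kept[key].to_numpy()
    frame = pd.DataFrame(frame_cols, index=kept.index)
    frame["fitted"] = fitted
    frame["residual"] = resid

    return FitResult(spec=spec, n=n, coef_table=coef, log_likelihood=float(loglik),
                     edf=float(edf_total), aic=float(aic), sigma2=float(sigma2),
                     tau2=tau2, r2_generalized=float(r2g), random_effects=re,
                     frame=frame, dropped_rows=dropped, beta=theta, cov=cov,
                     design=design)


def _coef_table(spec, design, theta, cov, n, edf) -> pd.DataFrame:
    rows = []
    df_resid = max(n - edf, 1.0)

    def add(label, est, var):
        se = float(np.sqrt(max(var, 0.0)))
        t = est / se if se > 0 else np.nan
        pval = 2.0 * stats.t.sf(abs(t), df_resid) if se > 0 else np.nan
        rows.append((label, float(est), se, float(t) if se > 0 else np.nan, pval))

    add("(Intercept)", theta[0], cov[0, 0])
    for term in spec.terms:
        sl = design.slices[term.name]
        if isinstance(term, (Smooth, Linear)):
            # report the linear (first-basis) component of the term
            j = sl.start
            add(term.name, theta[j], cov[j, j])
        elif isinstance(term, Factor):
            enc = design.encoders[term.name]
            W = enc.effect_weights()
            block = np.arange(sl.start, sl.stop)
            for lev, w in zip(enc.levels, W):
                est = float(w @ theta[block])
                var = float(w @ cov[np.ix_(block, block)] @ w)
                add(f"{term.name}[{lev}]", est, var)
        elif isinstance(term, SmoothByFactor):
            basis, coding = design.encoders[term.name]
            ncol = basis.ncol
            block = np.arange(sl.start, sl.stop)
            W = coding.effect_weights()
            for lev, w in zip(coding.levels, W):
                # linear component of this level's deviation smooth
                sel = np.zeros(len(block))
                for j in range(coding.ncol):
                    sel[j * ncol] = w[j]
                est = float(sel @ theta[block])
                var = float(sel @ cov[np.ix_(block, block)] @ sel)
                add(f"{term.name}[{lev}]", est, var)
    return pd.DataFrame(rows, columns=["term", "estimate", "std_error", "t", "p"])


# ---------------------------------------------------------------------------
# Partial effects


def partial_effect_table(fit: FitResult, term_name: str, grid=None,
                         level: Optional[str] = None) -> pd.DataFrame:
    """Centered partial effect of one term with pointwise SEs.

    For a :class:`Factor`, returns one row per level.  For a
    :class:`SmoothByFactor`, ``level`` selects the deviation curve.
    """
    spec = fit.spec
    design = fit.design
    term = next((t for t in spec.terms if t.name == term_name), None)
    if term is None:
        raise KeyError(f"term '{term_name}' not in model '{spec.name}'")
    sl = design.slices[term_name]
    block = np.arange(sl.start, sl.stop)
    covb = fit.cov[np.ix_(block, block)]
    beta = fit.beta[block]

    if isinstance(term, Factor):
        enc = design.encoders[term_name]
        W = enc.effect_weights()
        est = W @ beta
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", W, covb, W), 0, None))
        return pd.DataFrame({"level": enc.levels, "estimate": est, "std_error": se})

    if isinstance(term, (Smooth, Linear)):
        if grid is None:
            grid = np.asarray([], dtype=float)
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        if isinstance(term, Smooth):
            B = design.encoders[term_name].transform(grid)
        else:
            B = (grid - design.encoders[term_name][1])[:, None]
        est = B @ beta
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", B, covb, B), 0, None))
        return pd.DataFrame({"grid": grid, "estimate": est, "std_error": se})

    # SmoothByFactor deviation curve for one level
    basis, coding = design.encoders[term_name]
    if level is None or level not in coding.levels:
        raise KeyError(f"level required for '{term_name}'; one of {coding.levels}")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    Bv = basis.transform(grid)
    i = coding.levels.index(level)
    w = coding.effect_weights()[i]
    B = np.hstack([Bv * w[j] for j in range(coding.ncol)])
    est = B @ beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", B, covb, B), 0, None))
    return pd.DataFrame({"grid": grid, "estimate": est, "std_error": se})


# ---------------------------------------------------------------------------
# Model comparison, diagnostics


def compare_models(data: pd.DataFrame, specs: Sequence[ModelSpec]) -> pd.DataFrame:
    """Fit a ladder of specs on common complete rows; AIC table with dAIC.

    Rows missing any variable used by any spec are dropped before
    fitting so all models see identical data.  A failed fit is marked
    and the comparison proceeds.
    """
    all_vars = sorted({v for s in specs for v in s.variables()})
    common = _complete_rows(data, all_vars)
    rows = []
    for s in specs:
        try:
            fr = fit_additive_model(common, s)
            rows.append({"model": s.name, "edf": fr.edf, "aic": fr.aic,
                         "log_likelihood": fr.log_likelihood, "failed": False})
        except (FittingError, SingularDesignError) as exc:
            warnings.warn(f"model '{s.name}' failed: {exc}")
            rows.append({"model": s.name, "edf": np.nan, "aic": np.nan,
                         "log_likelihood": np.nan, "failed": True})
    out = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    out["daic"] = out["aic"] - out["aic"].min()
    return out


def residual_acf(fit: FitResult, max_lag: int = 48) -> AcfReport:
    """Sample autocorrelation of the fit residuals at lags 1..max_lag.

    Residuals are ordered by animal then time.  ``acf_within`` averages
    per-animal ACFs weighted by series length; ``acf_pooled`` is
    computed on the concatenated series.
    """
    frame = fit.frame
    if "animal_id" in frame.columns and "hour_start" in frame.columns:
        frame = frame.sort_values(["animal_id", "hour_start"])
    resid = frame["residual"].to_numpy()
    if np.var(resid) < 1e-14:
        raise FittingError("residuals are (near-)constant; ACF undefined")
    lags = np.arange(1, max_lag + 1)
    if "animal_id" in frame.columns:
        per, weights = [], []
        for _, gdf in frame.groupby("animal_id", sort=True):
            r = gdf["residual"].to_numpy()
            if len(r) > max_lag and np.var(r) > 1e-14:
                per.append(_sm_acf(r, nlags=max_lag, fft=True)[1:])
                weights.append(len(r))
        within = np.average(np.vstack(per), axis=0, weights=weights)
    else:
        within = _sm_acf(resid, nlags=max_lag, fft=True)[1:]
    pooled = _sm_acf(resid, nlags=max_lag, fft=True)[1:]
    return AcfReport(table=pd.DataFrame({"lag": lags, "acf_within": within,
                                         "acf_pooled": pooled}))


def subsample_refit(data: pd.DataFrame, spec: ModelSpec, n_per_group: int = 500,
                    seed: int = 0) -> SubsampleComparison:
    """Refit on a uniform without-replacement subsample per animal.

    Groups smaller than ``n_per_group`` contribute all their rows (with
    a warning).  Reports full and subsample coefficient tables side by
    side and the maximum absolute standardized difference
    (full - subsample) / SE_full.
    """
    rng = np.random.default_rng(seed)
    kept = _complete_rows(data, spec.variables())
    group_col = spec.random_intercept or "animal_id"
    parts = []
    for gid, gdf in kept.groupby(group_col, sort=True):
        if len(gdf) < n_per_group:
            warnings.warn(f"group {gid} has only {len(gdf)} rows; using all")
            parts.append(gdf)
        else:
            idx = rng.choice(len(gdf), size=n_per_group, replace=False)
            parts.append(gdf.iloc[np.sort(idx)])
    sub = pd.concat(parts)
    full_fit = fit_additive_model(kept, spec)
    sub_fit = fit_additive_model(sub, spec)
    comp = full_fit.coef_table.merge(sub_fit.coef_table, on="term",
                                     suffixes=("_full", "_sub"))
    # null variance of (full - sub) for a nested subsample is
    # se_sub^2 - se_full^2 (the full fit's information contains the
    # subsample's); when a coefficient's SE is dominated by shared
    # between-group structure that difference degenerates, so fall
    # back to the subsample SE as the scale
    extra = comp["std_error_sub"] ** 2 - comp["std_error_full"] ** 2
    denom = np.where(extra > 0.01 * comp["std_error_sub"] ** 2,
                     np.sqrt(np.clip(extra, 1e-300, None)),
                     comp["std_error_sub"])
    comp["std_diff"] = (comp["estimate_full"] - comp["estimate_sub"]) / denom
    return SubsampleComparison(comparison=comp,
                               max_abs_std_diff=float(comp["std_diff"].abs().max()),
                               full=full_fit, subsample=sub_fit)


# ---------------------------------------------------------------------------
# Effect-size summaries of a fitted model


def activity_effect_estimate(fit: FitResult, data: pd.DataFrame,
                             term: str = "s(activity_minutes)") -> float:
    """Heart-rate increase (bpm) at a fully active hour (60 active min).

    Estimated as 60 x the least-squares slope of the activity partial
    effect, weighted by the observed activity distribution — far more
    stable than extrapolating the spline to 60 min when high activity
    is rare.
    """
    a = data["activity_minutes"].dropna().to_numpy()
    grid = np.arange(0.0, a.max() + 1.0)
    pe = partial_effect_table(fit, term, grid)
    w = np.bincount(a.astype(int), minlength=len(grid)).astype(float)
    xbar = np.average(grid, weights=w)
    slope = (np.average((grid - xbar) * pe["estimate"].to_numpy(), weights=w)
             / np.average((grid - xbar) ** 2, weights=w))
    return float(60.0 * slope)


def hour_amplitude_estimate(fit: FitResult, term: str = "s(hour)") -> float:
    """Half peak-to-trough range of the shared hour smooth (bpm)."""
    pe = partial_effect_table(fit, term, np.arange(24.0))
    return float((pe["estimate"].max() - pe["estimate"].min()) / 2.0)


def season_effects_estimate(fit: FitResult, term: str = "season") -> pd.Series:
    """Sum-to-zero season effects (bpm) from the fitted factor term."""
    pe = partial_effect_table(fit, term)
    return pd.Series(pe["estimate"].to_numpy(), index=pe["level"].tolist())


# ---------------------------------------------------------------------------
# The standard model ladder


def prepare_model_frame(hourly_joined: pd.DataFrame) -> pd.DataFrame:
    """Add the derived ``hour`` column used by the hour smooths."""
    out = hourly_joined.copy()
    out["hour"] = pd.to_datetime(out["hour_start"]).dt.hour.astype(float)
    return out


def standard_ladder(activity_df: int = 3, hour_df: int = 6, temp_df: int = 3,
                    daylength_df: int = 3, interaction_df: int = 3,
                    random_intercept: str = "animal_id") -> list:
    """The nine-model comparison ladder, null through full interaction.

    Models are nested combinations of an activity smooth, hour smooth,
    season factor, temperature smooth, day-length smooth and the
    hour-by-season interaction, each with the per-animal random
    intercept.
    """
    act = Smooth("activity_minutes", activity_df)
    hour = Smooth("hour", hour_df)
    temp = Smooth("temp_f", temp_df)
    dayl = Smooth("day_length_h", daylength_df)
    season = Factor("season")
    inter = SmoothByFactor("hour", "season", interaction_df)
    re = random_intercept
    return [
        ModelSpec("hrm0", (), re),
        ModelSpec("hrm1", (act,), re),
        ModelSpec("hrm2", (act, temp), re),
        ModelSpec("hrm3", (act, temp, dayl), re),
        ModelSpec("hrm4", (act, hour), re),
        ModelSpec("hrm5", (act, hour, temp), re),
        ModelSpec("hrm6", (act, hour, season), re),
        ModelSpec("hrm7", (act, hour, season, temp), re),
        ModelSpec("hrm8", (act, hour, season, inter, temp), re),
    ]
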