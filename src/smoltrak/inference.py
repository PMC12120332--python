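"""Statistical model suite for the migration-success analysis.

Individual-level: binomial GLMM of per-fish success on tag burden and body
condition with crossed river/year random intercepts, screened by VIF and
reduced by likelihood-ratio step-down.  Population-level: gamma GLM for
speed, chi-square test of temporal change, Kendall's W for between-river
concordance, Levene's test for stability of the rate of migration success,
a beta regression of the rate on landscape/geology covariates with
Tukey-adjusted bedrock contrasts and distance-standardized marginal-effect
curves, and a beta GLMM of the rate on discharge percentage exceedance with
a river random intercept.

The classical tests (VIF, chi-square goodness-of-fit, Kendall's W, Levene)
are implemented here directly; ordinary GLM / beta-regression likelihoods
come from statsmodels, and the mixed models from :mod:`smoltrak.glmm`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .glmm import GLMMFit, fit_glmm
from .migration import STANDARD_DISTANCE_KM, standardize_rate

BEDROCK_LEVELS = ("igneous", "metamorphic", "sedimentary")
DEFAULT_LANDSCAPE_CANDIDATES = (
    "grassland", "woodland", "wetland", "urban", "agricultural",
    "peat", "area_km2", "gradient", "barriers", "bedrock",
)


@dataclass
class ModelFit:
    """Uniform wrapper around fitted models for likelihood-ratio work."""

    name: str
    family: str
    params: pd.Series
    bse: pd.Series
    loglik: float
    df_model: int          # parameter count entering LRT df arithmetic
    n: int
    terms: tuple = ()
    extra: dict = field(default_factory=dict)

    def wald_ci(self, level=0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"estimate": self.params, "lo": self.params - z * self.bse,
             "hi": self.params + z * self.bse}
        )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


def lrt(nested: ModelFit, full: ModelFit) -> LRTResult:
    """Likelihood-ratio test of a nested model against the full model.

    ``statistic = 2 * (LL_full - LL_nested)``; small negative values from
    numerical optimization are clamped to zero.  Identical models yield
    statistic 0, df 0, p 1.
    """
    if not set(nested.terms) <= set(full.terms):
        raise ValueError(f"models are not nested: {nested.terms} vs {full.terms}")
    if nested.df_model > full.df_model:
        raise ValueError("nested model has more parameters than the full model")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6 * (1.0 + abs(full.loglik)):
        warnings.warn(f"nested log-likelihood exceeds the full model's by {-stat / 2:.4g}; "
                      "optimization noise or mis-specified nesting")
    stat = max(stat, 0.0)
    df = full.df_model - nested.df_model
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=int(df), p=p)


# ----------------------------------------------------------------------
# design-matrix helpers

def _term_columns(data: pd.DataFrame, term: str):
    """Columns a term contributes: categorical terms expand to dummies."""
    if term == "bedrock" or data[term].dtype == object or isinstance(data[term].dtype, pd.CategoricalDtype):
        levels = sorted(data[term].astype(str).unique())
        cols = {}
        for lev in levels[1:]:  # first level is the reference
            cols[f"{term}[{lev}]"] = (data[term].astype(str) == lev).astype(float).to_numpy()
        return cols
    return {term: pd.to_numeric(data[term]).to_numpy(dtype=float)}


def build_design(data: pd.DataFrame, terms: Sequence[str]):
    cols = {"Intercept": np.ones(len(data))}
    for t in terms:
        cols.update(_term_columns(data, t))
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


# ----------------------------------------------------------------------
# individual-level success model (binomial GLMM)

def fit_individual_success(data: pd.DataFrame, terms: Sequence[str] = ("tag_burden", "condition"),
                           response: str = "succeeded",
                           random: Sequence[str] = ("river", "year")) -> ModelFit:
    """Binomial GLMM of individual migration success.

    ``data`` carries one row per fish with the response (0/1), the covariate
    columns in ``terms``, and the grouping columns in ``random`` (river and
    year as crossed random intercepts).  Requires at least two levels in
    each random factor.
    """
    for g in random:
        if data[g].nunique() < 2:
            raise ValueError(f"random factor {g!r} needs >= 2 levels, got {data[g].nunique()}")
    sub = data.dropna(subset=[response, *terms])
    X, names = build_design(sub, terms)
    fit = fit_glmm(sub[response].astype(float).to_numpy(), X,
                   groups={g: sub[g].to_numpy() for g in random},
                   family="binomial", feature_names=names)
    return ModelFit(
        name="individual_success", family=f"binomial(logit)+(1|{')(1|'.join(random)})",
        params=fit.params, bse=fit.bse, loglik=fit.loglik,
        df_model=fit.df_model, n=fit.n, terms=tuple(terms),
        extra={"sigmas": fit.sigmas, "glmm": fit},
    )


def step_down(fit_fn, data: pd.DataFrame, terms: Sequence[str], alpha: float = 0.05):
    """Backward likelihood-ratio selection.

    Each round drops the term whose removal has the largest LRT p-value
    above ``alpha`` (ties broken toward the term contributing fewer
    parameters); stops when every remaining term is significant.  Returns
    ``(final_fit, trace)`` where the trace records every removal test.
    """
    current = list(terms)
    full = fit_fn(data, tuple(current))
    trace = []
    while current:
        tests = []
        for t in current:
            reduced = fit_fn(data, tuple(x for x in current if x != t))
            r = lrt(reduced, full)
            tests.append((t, r, reduced))
            trace.append({"dropped": t, "from": tuple(current), "statistic": r.statistic,
                          "df": r.df, "p": r.p})
        tests.sort(key=lambda x: (-x[1].p, x[1].df))
        name, res, reduced = tests[0]
        if res.p > alpha:
            current.remove(name)
            full = reduced
        else:
            break
    return full, pd.DataFrame(trace)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: 1 / (1 - R^2) of each covariate regressed
    on all the others (with an intercept).  Perfect collinearity reports
    infinity."""
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs >= 2 covariates")
    M = design.to_numpy(dtype=float)
    if np.any(M.std(axis=0) == 0):
        raise ValueError("VIF is undefined for constant columns")
    out = {}
    for j, name in enumerate(cols):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(len(M)), np.delete(M, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ----------------------------------------------------------------------
# speed (gamma GLM) and spatial success (binomial GLM)

def _wrap_glm(results, name, family, terms):
    return ModelFit(name=name, family=family, params=results.params, bse=results.bse,
                    loglik=float(results.llf), df_model=int(results.df_model + 1),
                    n=int(results.nobs), terms=tuple(terms), extra={"results": results})


def _glm_terms(data, terms, y, fam, name, famname):
    X, names = build_design(data, terms)
    res = sm.GLM(y, pd.DataFrame(X, columns=names, index=data.index), family=fam).fit()
    return _wrap_glm(res, name, famname, terms)


def fit_speed_glm(outcomes: pd.DataFrame):
    """Gamma GLM (log link) of migration speed; river and year are each
    tested against the intercept-only model by LRT.

    Returns a dict with the null fit, each single-factor fit, and the two
    LRT results.  Non-positive speeds are a domain error.
    """
    sub = outcomes.dropna(subset=["speed_km_per_day"]).copy()
    if (sub["speed_km_per_day"] <= 0).any():
        raise ValueError("speeds must be strictly positive")
    y = sub["speed_km_per_day"].to_numpy(dtype=float)
    fam = sm.families.Gamma(link=sm.families.links.Log())
    sub["river"] = sub["river"].astype(str)
    sub["year"] = sub["year"].astype(str)
    null = _glm_terms(sub, (), y, fam, "speed_null", "gamma(log)")
    by_river = _glm_terms(sub, ("river",), y, fam, "speed_river", "gamma(log)")
    by_year = _glm_terms(sub, ("year",), y, fam, "speed_year", "gamma(log)")
    return {
        "null": null, "river": by_river, "year": by_year,
        "lrt_river": lrt(null, by_river), "lrt_year": lrt(null, by_year),
    }


def fit_success_spatial(summaries: pd.DataFrame):
    """Binomial GLM of population success counts on river, tested against
    the intercept-only model (spatial variation in success)."""
    df = summaries.copy()
    df["river"] = df["river"].astype(str)
    endog = np.column_stack([df["n_succeeded"], df["n_entered"] - df["n_succeeded"]])
    fam = sm.families.Binomial()
    X0, n0 = build_design(df, ())
    X1, n1 = build_design(df, ("river",))
    null = _wrap_glm(sm.GLM(endog, pd.DataFrame(X0, columns=n0), family=fam).fit(),
                     "success_null", "binomial(logit)", ())
    by_river = _wrap_glm(sm.GLM(endog, pd.DataFrame(X1, columns=n1), family=fam).fit(),
                         "success_river", "binomial(logit)", ("river",))
    return {"null": null, "river": by_river, "lrt_river": lrt(null, by_river)}


# ----------------------------------------------------------------------
# temporal tests

def temporal_chisq(counts: pd.DataFrame):
    """Chi-square goodness-of-fit of later-year success against each
    river's first-year proportion.

    ``counts`` needs river, year, n_entered, n_succeeded.  For each river
    with >= 2 years, expected successes in later years are the first-year
    proportion times that year's entrants; the statistic sums (O - E)^2 / E
    over the success and failure cells of every later river-year, with df
    equal to the number of later river-years.
    """
    stat, df = 0.0, 0
    for river, grp in counts.groupby("river"):
        grp = grp.sort_values("year")
        if len(grp) < 2:
            continue
        first = grp.iloc[0]
        p1 = first["n_succeeded"] / first["n_entered"]
        for _, row in grp.iloc[1:].iterrows():
            n = row["n_entered"]
            e_s, e_f = p1 * n, (1.0 - p1) * n
            if e_s <= 0 or e_f <= 0:
                raise ValueError(
                    f"{river} {row['year']}: expected cell of zero (first-year proportion {p1}); "
                    "exclude this river from the temporal test"
                )
            o_s = row["n_succeeded"]
            stat += (o_s - e_s) ** 2 / e_s + ((n - o_s) - e_f) ** 2 / e_f
            df += 1
    if df == 0:
        raise ValueError("no river has >= 2 years of data")
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def kendalls_w(success: pd.DataFrame, return_submatrix: bool = False):
    """Kendall's coefficient of concordance for migration success across
    rivers, with years as the ranking "judges".

    ``success`` is a wide rivers x years table (NaN = not measured).  Year
    coverage is unbalanced, so W is computed on the largest complete
    river x year submatrix (most cells; ties favour more years).  Ties in
    the within-year rankings use average ranks with the standard tie
    correction; the p-value uses the chi-square approximation
    ``chi2 = k (n - 1) W`` on n - 1 df.
    """
    years = list(success.columns)
    if len(years) >= 2 and len(success) >= 2 and not success.isna().any().any():
        best = success  # already complete: no submatrix search needed
        return _kendalls_w_complete(best, return_submatrix)
    best, best_key = None, (-1, -1)
    for r in range(2, len(years) + 1):
        for combo in itertools.combinations(years, r):
            sub = success[list(combo)].dropna(axis=0, how="any")
            if len(sub) < 2:
                continue
            key = (len(sub) * r, r)
            if key > best_key:
                best, best_key = sub, key
    if best is None:
        raise ValueError("need >= 2 rivers and >= 2 years with complete overlap")
    return _kendalls_w_complete(best, return_submatrix)


def _kendalls_w_complete(best: pd.DataFrame, return_submatrix: bool):
    n, k = best.shape
    ranks = best.rank(axis=0)
    R = ranks.sum(axis=1).to_numpy()
    S = float(((R - k * (n + 1) / 2.0) ** 2).sum())
    ties = 0.0
    for col in ranks.columns:
        _, cnt = np.unique(best[col].to_numpy(), return_counts=True)
        ties += float((cnt**3 - cnt).sum())
    denom = k**2 * (n**3 - n) - k * ties
    W = 12.0 * S / denom if denom > 0 else np.nan
    chi2 = k * (n - 1) * W
    p = float(stats.chi2.sf(chi2, n - 1))
    if return_submatrix:
        return float(W), p, best
    return float(W), p


def levene_rate_variance(values, groups, center: str = "median"):
    """Levene/Brown-Forsythe test for equal spread of the rate of migration
    success across rivers: one-way ANOVA on absolute deviations from the
    group center (median by default, matching common practice; ``"mean"``
    gives the classical Levene form).

    Groups of size one contribute zero spread but are kept in the group
    count, mirroring how unbalanced river-year designs are usually tested.
    Returns ``(F, df1, df2, p)``.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    if df["g"].nunique() < 2:
        raise ValueError("need >= 2 groups")
    if (df.groupby("g")["y"].size() == 1).all():
        raise ValueError("all groups have a single observation; spread is undefined")
    centerer = np.median if center == "median" else np.mean
    z = df.groupby("g")["y"].transform(lambda s: np.abs(s - centerer(s.to_numpy())))
    k = df["g"].nunique()
    N = len(df)
    zbar = z.mean()
    group_means = z.groupby(df["g"]).mean()
    group_sizes = df.groupby("g").size()
    ss_between = float((group_sizes * (group_means - zbar) ** 2).sum())
    ss_within = float(((z - z.groupby(df["g"]).transform("mean")) ** 2).sum())
    df1, df2 = k - 1, N - k
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df1) / (ss_within / df2)
    return float(F), int(df1), int(df2), float(stats.f.sf(F, df1, df2))


# ----------------------------------------------------------------------
# beta regressions on the rate of migration success

def squeeze_unit_interval(y, n: Optional[int] = None):
    """Smithson-Verkuilen boundary squeeze ``y' = (y (n - 1) + 0.5) / n``,
    applied only when the response touches 0 or 1."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = len(y)
    if ((y <= 0) | (y >= 1)).any():
        return (y * (n - 1) + 0.5) / n
    return y


def _fit_beta_glm(data, terms, response):
    from statsmodels.othermod.betareg import BetaModel

    y = data[response].to_numpy(dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError("rates on the [0,1] boundary: apply squeeze_unit_interval first "
                         "(or pass squeeze='auto')")
    X, names = build_design(data, terms)
    exog = pd.DataFrame(X, columns=names, index=data.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BetaModel(y, exog, exog_precision=np.ones((len(y), 1))).fit(disp=False, maxiter=500)
    params = res.params.iloc[:-1]  # final parameter is the log-precision
    bse = res.bse.iloc[:-1]
    return ModelFit(
        name="rate_landscape", family="beta(logit)",
        params=params, bse=bse, loglik=float(res.llf),
        df_model=len(params) + 1, n=len(y), terms=tuple(terms),
        extra={"results": res, "precision": float(np.exp(res.params.iloc[-1])), "data": data,
               "response": response},
    )


def fit_rate_landscape(data: pd.DataFrame,
                       candidates: Sequence[str] = DEFAULT_LANDSCAPE_CANDIDATES,
                       response: str = "rate_per_km", alpha: float = 0.05,
                       squeeze: str = "auto", select: bool = True):
    """Beta regression (logit link) of the per-km rate of migration success
    on catchment landscape/geology covariates, reduced by LRT step-down.

    ``data`` joins the per-river(-year) rate with the catchment covariate
    table.  Returns ``(final ModelFit, selection trace)``; with
    ``select=False`` the full candidate model is returned with an empty
    trace.
    """
    data = data.copy()
    candidates = tuple(t for t in candidates if t in data.columns)
    y = data[response].to_numpy(dtype=float)
    if squeeze == "auto":
        data[response] = squeeze_unit_interval(y)
    fit_fn = lambda d, terms: _fit_beta_glm(d, terms, response)
    if not select:
        return fit_fn(data, candidates), pd.DataFrame()
    return step_down(fit_fn, data, candidates, alpha=alpha)


def kfold_check(data: pd.DataFrame, terms: Sequence[str], response: str = "rate_per_km",
                k: int = 5, seed: int = 0) -> dict:
    """Simple k-fold overfitting check for the landscape beta regression.

    Fits the model on k−1 folds and scores mean absolute prediction error
    on the held-out fold; a held-out error far above the in-sample error
    flags overfitting.  Returns in/out-of-sample MAE and their ratio.
    """
    data = data.copy()
    data[response] = squeeze_unit_interval(data[response].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(data))
    folds = np.array_split(idx, k)
    in_err, out_err = [], []
    for f in folds:
        test = data.iloc[f]
        train = data.drop(data.index[f])
        fit = _fit_beta_glm(train, tuple(terms), response)
        Xtr, names = build_design(train, fit.terms)
        Xte, _ = build_design(test, fit.terms)
        beta = fit.params.to_numpy()
        in_err.append(np.mean(np.abs(expit(Xtr @ beta) - train[response])))
        out_err.append(np.mean(np.abs(expit(Xte @ beta) - test[response])))
    mae_in, mae_out = float(np.mean(in_err)), float(np.mean(out_err))
    return {"mae_in_sample": mae_in, "mae_out_of_sample": mae_out,
            "ratio": mae_out / mae_in if mae_in > 0 else np.inf, "k": k}


def marginal_effects(fit: ModelFit, covariate: str, grid=None,
                     standard_km: float = STANDARD_DISTANCE_KM, n_grid: int = 50) -> pd.DataFrame:
    """Predicted standardized migration success across one covariate.

    Other continuous covariates are held at their observed means and
    categorical terms at their observed frequencies; predictions are the
    per-km rate transformed to the common reference distance.  The band is
    the link-scale mean +/- 2 SD, transformed the same way.  A grid outside
    the observed range only warns.
    """
    if covariate not in fit.terms:
        raise ValueError(f"{covariate!r} is not a term of the fitted model {fit.terms}")
    data = fit.extra["data"]
    obs = pd.to_numeric(data[covariate]).to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(obs.min(), obs.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < obs.min() - 1e-12 or grid.max() > obs.max() + 1e-12:
        warnings.warn(f"grid extends beyond the observed range of {covariate}")

    X, names = build_design(data, fit.terms)
    Xbar = X.mean(axis=0)  # dummies at observed frequencies, covariates at means
    G = np.tile(Xbar, (len(grid), 1))
    j = names.index(covariate)
    G[:, j] = grid

    res = fit.extra["results"]
    V = np.asarray(res.cov_params())[: len(names), : len(names)]
    eta = G @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, V, G))
    out = pd.DataFrame(
        {covariate: grid, "rate_per_km": expit(eta),
         "success_std": expit(eta) ** standard_km,
         "lo": expit(eta - 2 * se) ** standard_km,
         "hi": expit(eta + 2 * se) ** standard_km}
    )
    return out


def bedrock_pairwise(fit: ModelFit, term: str = "bedrock") -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of the estimated marginal means of
    the bedrock categories (on the link scale, other covariates at their
    observed means).  A level absent from the data is reported inestimable
    (NaN row)."""
    if term not in fit.terms:
        raise ValueError(f"{term!r} is not in the fitted model")
    data = fit.extra["data"]
    X, names = build_design(data, fit.terms)
    Xbar = X.mean(axis=0)
    levels = sorted(data[term].astype(str).unique())
    k = len(BEDROCK_LEVELS) if term == "bedrock" else len(levels)

    def emm_row(level):
        row = Xbar.copy()
        for nm in names:
            if nm.startswith(f"{term}["):
                row[names.index(nm)] = 1.0 if nm == f"{term}[{level}]" else 0.0
        return row

    res = fit.extra["results"]
    V = np.asarray(res.cov_params())[: len(names), : len(names)]
    beta = fit.params.to_numpy()
    dfree = max(fit.n - fit.df_model, 1)
    rows = []
    all_levels = BEDROCK_LEVELS if term == "bedrock" else tuple(levels)
    for a, b in itertools.combinations(all_levels, 2):
        if a not in levels or b not in levels:
            rows.append({"contrast": f"{a} - {b}", "estimate": np.nan, "se": np.nan,
                         "t": np.nan, "p_tukey": np.nan, "estimable": False})
            continue
        c = emm_row(a) - emm_row(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        t = est / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), len(levels), dfree))
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se, "t": t,
                     "p_tukey": min(max(p, 0.0), 1.0), "estimable": True})
    return pd.DataFrame(rows)


def fit_rate_exceedance(data: pd.DataFrame, response: str = "rate_per_km",
                        exceedance: str = "exceedance", river: str = "river",
                        squeeze: str = "auto"):
    """Beta GLMM (logit link) of the rate of migration success on discharge
    percentage exceedance with a river random intercept, restricted to
    rivers observed in more than one year; the exceedance effect is tested
    by LRT against the intercept-only mixed model.

    With a single river the random intercept is degenerate and the model
    falls back to a fixed-intercept beta regression (with a warning).
    Returns ``(full ModelFit, LRTResult)``.
    """
    counts = data.groupby(river)[response].size()
    keep = counts[counts > 1].index
    sub = data[data[river].isin(keep)].copy()
    if len(sub) == 0:
        raise ValueError("no river has more than one year of data")
    y = sub[response].to_numpy(dtype=float)
    if squeeze == "auto":
        y = squeeze_unit_interval(y)
        sub[response] = y

    if sub[river].nunique() < 2:
        warnings.warn("single river: random intercept degenerate, using fixed-intercept beta GLM")
        full = _fit_beta_glm(sub, (exceedance,), response)
        null = _fit_beta_glm(sub, (), response)
        return full, lrt(null, full)

    groups = {river: sub[river].to_numpy()}
    x = sub[exceedance].to_numpy(dtype=float)
    X1 = np.column_stack([np.ones(len(sub)), x])
    X0 = np.ones((len(sub), 1))
    f1 = fit_glmm(y, X1, groups, family="beta", feature_names=["Intercept", exceedance])
    f0 = fit_glmm(y, X0, groups, family="beta", feature_names=["Intercept"], se=False)
    full = ModelFit(name="rate_exceedance", family="beta(logit)+(1|river)",
                    params=f1.params, bse=f1.bse, loglik=f1.loglik, df_model=f1.df_model,
                    n=f1.n, terms=(exceedance,), extra={"sigmas": f1.sigmas, "glmm": f1})
    null = ModelFit(name="rate_exceedance_null", family="beta(logit)+(1|river)",
                    params=f0.params, bse=f0.bse, loglik=f0.loglik, df_model=f0.df_model,
                    n=f0.n, terms=(), extra={"sigmas": f0.sigmas, "glmm": f0})
    return full, lrt(null, full)
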