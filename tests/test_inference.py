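"""Statistical suite: classical tests against hand/scipy oracles, model
selection behaviour, beta-regression machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

import smoltrak as st
from smoltrak.inference import ModelFit, _fit_beta_glm

warnings.filterwarnings("ignore", message=".*efficiency undefined.*")


# ---------------------------------------------------------------- VIF

def test_vif_orthogonal_and_collinear():
    rng = np.random.default_rng(0)
    a = rng.normal(size=400)
    b = rng.normal(size=400)
    a, b = a - a.mean(), b - b.mean()
    b = b - a * (a @ b) / (a @ a)  # exactly orthogonal
    v = st.vif(pd.DataFrame({"a": a, "b": b}))
    assert np.allclose(v, 1.0, atol=1e-10)
    v2 = st.vif(pd.DataFrame({"a": a, "b": b, "dup": a}))
    assert np.isinf(v2["a"]) and np.isinf(v2["dup"])


def test_vif_known_correlation_and_statsmodels_oracle():
    rng = np.random.default_rng(1)
    z = rng.multivariate_normal([0, 0], [[1, 0.25], [0.25, 1]], size=200_00)
    v = st.vif(pd.DataFrame(z, columns=["a", "b"]))
    assert v["a"] == pytest.approx(1.0 / (1 - 0.25**2), abs=0.01)  # ~1.07
    # independent oracle on a small instance
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
    X["b"] += 0.7 * X["a"]
    mine = st.vif(X)
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    for j, name in enumerate(X.columns):
        assert mine[name] == pytest.approx(variance_inflation_factor(design, j + 1), abs=1e-8)


def test_vif_usage_errors():
    with pytest.raises(ValueError, match=">= 2"):
        st.vif(pd.DataFrame({"a": [1.0, 2.0]}))
    with pytest.raises(ValueError, match="constant"):
        st.vif(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]}))


# ---------------------------------------------------------------- LRT

def _fake_fit(ll, k, terms):
    return ModelFit(name="m", family="f", params=pd.Series(np.zeros(k)),
                    bse=pd.Series(np.zeros(k)), loglik=ll, df_model=k, n=10, terms=terms)


def test_lrt_identical_models():
    m = _fake_fit(-12.3, 2, ("a",))
    r = st.lrt(m, m)
    assert r.statistic == 0.0 and r.p == 1.0


def test_lrt_closed_form():
    nested, full = _fake_fit(-105.0, 1, ()), _fake_fit(-100.0, 3, ("a", "b"))
    r = st.lrt(nested, full)
    assert r.statistic == pytest.approx(10.0)
    assert r.df == 2
    assert r.p == pytest.approx(float(stats.chi2.sf(10.0, 2)), abs=1e-12)


def test_lrt_rejects_non_nested():
    with pytest.raises(ValueError, match="not nested"):
        st.lrt(_fake_fit(-10, 2, ("a",)), _fake_fit(-9, 2, ("b",)))
    with pytest.raises(ValueError, match="more parameters"):
        st.lrt(_fake_fit(-10, 5, ("a",)), _fake_fit(-9, 2, ("a", "b")))


# ---------------------------------------------------- temporal chi-square

def _counts(rows):
    return pd.DataFrame(rows, columns=["river", "year", "n_entered", "n_succeeded"])


def test_temporal_chisq_identical_years_zero():
    c = _counts([("A", 2019, 100, 40), ("A", 2020, 50, 20), ("A", 2021, 200, 80)])
    stat, df, p = st.temporal_chisq(c)
    assert stat == pytest.approx(0.0, abs=1e-12) and df == 2 and p == pytest.approx(1.0)


def test_temporal_chisq_hand_arithmetic():
    # first year p1 = 0.5; later year observes 30 successes / 70 failures
    # of 100: (30-50)^2/50 + (70-50)^2/50 = 8 + 8 = 16
    c = _counts([("A", 2019, 100, 50), ("A", 2020, 100, 30)])
    stat, df, p = st.temporal_chisq(c)
    assert stat == pytest.approx(16.0)
    assert df == 1
    assert p == pytest.approx(float(stats.chi2.sf(16.0, 1)))


def test_temporal_chisq_study_design_df():
    # the multi-year study layout: 14 cohort series (two release groups on
    # one river kept separate, one river excluded for a failed first
    # receiver) -> 20 later-year river-years
    t2 = st.load_migration_summaries()
    t1 = st.load_cohort_summaries()
    multi = t2.groupby("river").filter(lambda g: len(g) > 1)
    m = multi.merge(t1[["river", "year", "n_tagged"]], on=["river", "year"])
    m = m[m["river"] != "Gryffe"]
    m = m.assign(n_entered=m["n_tagged"],
                 n_succeeded=(m["migration_success"] * m["n_tagged"]).round().astype(int))
    stat, df, p = st.temporal_chisq(m)
    assert df == 20
    assert p < 0.001


def test_temporal_chisq_zero_expected_cell():
    c = _counts([("A", 2019, 100, 0), ("A", 2020, 100, 30)])
    with pytest.raises(ValueError, match="expected cell"):
        st.temporal_chisq(c)


# ---------------------------------------------------------- Kendall's W

def test_kendalls_w_perfect_and_reversed():
    perfect = pd.DataFrame({2019: [0.1, 0.4, 0.7, 0.9], 2020: [0.2, 0.5, 0.8, 0.95]},
                           index=list("abcd"))
    W, _ = st.kendalls_w(perfect)
    assert W == pytest.approx(1.0)
    reversed_ = pd.DataFrame({2019: [1.0, 2.0, 3.0, 4.0], 2020: [4.0, 3.0, 2.0, 1.0]},
                             index=list("abcd"))
    W, p = st.kendalls_w(reversed_)
    assert W == pytest.approx(0.0, abs=1e-12)


def test_kendalls_w_null_mean_matches_permutation_expectation():
    # under random rankings E[W] = 1/k exactly (k judges)
    rng = np.random.default_rng(5)
    k, n = 13, 8
    ws = []
    for _ in range(400):
        m = pd.DataFrame(rng.uniform(size=(n, k)), columns=[2000 + j for j in range(k)])
        ws.append(st.kendalls_w(m)[0])
    assert np.mean(ws) == pytest.approx(1.0 / k, abs=0.0075)


def test_kendalls_w_incomplete_matrix_uses_largest_complete_block():
    m = pd.DataFrame({2019: [0.1, 0.2, np.nan, 0.5], 2020: [0.2, 0.3, 0.4, 0.6],
                      2021: [0.15, 0.35, 0.5, np.nan]}, index=list("abcd"))
    W, p, sub = st.kendalls_w(m, return_submatrix=True)
    assert sub.notna().all().all()
    assert sub.size >= 6  # 3 rivers x 2 years at least


def test_kendalls_w_usage_error():
    with pytest.raises(ValueError):
        st.kendalls_w(pd.DataFrame({2019: [0.1, 0.2]}))  # single year


# ---------------------------------------------------------- Levene

def test_levene_equal_spread_and_scipy_oracle():
    rng = np.random.default_rng(7)
    y = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20), rng.normal(-3, 1, 20)])
    g = np.repeat(list("abc"), 20)
    F, df1, df2, p = st.levene_rate_variance(y, g, center="median")
    F_sp, p_sp = stats.levene(y[:20], y[20:40], y[40:], center="median")
    assert F == pytest.approx(float(F_sp), abs=1e-8)
    assert p == pytest.approx(float(p_sp), abs=1e-10)


def test_levene_detects_inflated_group():
    rng = np.random.default_rng(8)
    y = np.concatenate([rng.normal(0, 10, 10), rng.normal(0, 1, 15), rng.normal(0, 1, 15)])
    g = np.array(["wide"] * 10 + ["a"] * 15 + ["b"] * 15)
    F, df1, df2, p = st.levene_rate_variance(y, g)
    assert p < 0.01


def test_levene_hand_example():
    # two small groups: the statistic is a one-way ANOVA on the absolute
    # deviations from the group means, computed here by brute force
    y = np.array([0.0, 2.0, 6.0, 0.0, 4.0, 1.0, 9.0])
    g = np.array(["a", "a", "a", "b", "b", "b", "b"])
    F, df1, df2, p = st.levene_rate_variance(y, g, center="mean")
    z_a = np.abs(y[:3] - y[:3].mean())
    z_b = np.abs(y[3:] - y[3:].mean())
    F_hand, p_hand = stats.f_oneway(z_a, z_b)
    assert df1 == 1 and df2 == 5
    assert F == pytest.approx(float(F_hand), abs=1e-10)
    assert p == pytest.approx(float(p_hand), abs=1e-12)


def test_levene_usage_errors():
    with pytest.raises(ValueError, match=">= 2"):
        st.levene_rate_variance([1.0, 2.0], ["a", "a"])
    with pytest.raises(ValueError, match="single observation"):
        st.levene_rate_variance([1.0, 2.0], ["a", "b"])


# ---------------------------------------------------------- speed GLM

def test_speed_glm_null_identity_and_group_difference():
    rng = np.random.default_rng(9)
    speeds = np.concatenate([rng.gamma(9, 1.0, 100), rng.gamma(9, 5.0, 100)])
    oc = pd.DataFrame({"speed_km_per_day": speeds, "river": ["A"] * 100 + ["B"] * 100,
                       "year": [2019, 2020] * 100})
    out = st.fit_speed_glm(oc)
    # intercept-only gamma GLM with log link reproduces the sample mean
    assert np.exp(out["null"].params["Intercept"]) == pytest.approx(speeds.mean(), rel=1e-6)
    assert out["lrt_river"].p < 1e-6  # 5x mean ratio
    assert out["lrt_year"].p > 0.05


def test_speed_glm_homogeneous_groups_not_significant():
    rng = np.random.default_rng(10)
    oc = pd.DataFrame({"speed_km_per_day": rng.gamma(9, 1.0, 300),
                       "river": np.repeat(list("abc"), 100), "year": 2019 + (np.arange(300) % 3)})
    out = st.fit_speed_glm(oc)
    assert out["lrt_river"].p > 0.05


def test_speed_glm_rejects_nonpositive():
    oc = pd.DataFrame({"speed_km_per_day": [1.0, -2.0], "river": ["A", "A"], "year": [2019, 2019]})
    with pytest.raises(ValueError, match="positive"):
        st.fit_speed_glm(oc)


def test_spatial_success_glm_detects_river_differences():
    summ = pd.DataFrame({"river": list("abcd"), "n_entered": [100] * 4,
                         "n_succeeded": [90, 20, 70, 40]})
    out = st.fit_success_spatial(summ)
    assert out["lrt_river"].df == 3
    assert out["lrt_river"].p < 1e-6


# ------------------------------------------------- beta regression layer

def _landscape_data(seed, n=100, phi=400.0, noise_cov=False):
    cfg = st.SimConfig(n_rivers=n, seed=seed)
    catch = st.generate_catchments(cfg)
    rng = np.random.default_rng(seed + 10_000)
    mu = np.array([st.true_rate_per_km(r, cfg) for _, r in catch.iterrows()])
    mu = np.clip(mu, 1e-4, 1 - 1e-4)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    data = catch.assign(rate_per_km=y)
    if noise_cov:
        data["noise"] = rng.normal(size=n)
    return data


def test_beta_single_covariate_quasi_deterministic():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 1, 400)
    mu = expit(1.0 - 2.0 * x)
    y = rng.beta(mu * 20_000, (1 - mu) * 20_000)
    fit = _fit_beta_glm(pd.DataFrame({"rate_per_km": y, "x": x}), ("x",), "rate_per_km")
    assert fit.params["x"] == pytest.approx(-2.0, abs=0.005)
    assert fit.params["Intercept"] == pytest.approx(1.0, abs=0.005)


def test_step_down_eliminates_pure_noise_covariate():
    # mid-range beta responses so the chi-square reference for the removal
    # LRTs is well calibrated; the true model has two real terms plus noise
    removed, kept_real = 0, 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 100
        g = rng.uniform(0, 0.6, n)
        w = rng.uniform(0, 0.5, n)
        mu = expit(1.2 - 2.5 * g + 2.0 * w)
        data = pd.DataFrame({"rate_per_km": rng.beta(mu * 200, (1 - mu) * 200),
                             "grassland": g, "wetland": w, "noise": rng.normal(size=n)})
        fit, trace = st.fit_rate_landscape(data, candidates=("grassland", "wetland", "noise"))
        removed += "noise" not in fit.terms
        kept_real += {"grassland", "wetland"} <= set(fit.terms)
        # step-down never removes a term whose final removal LRT has p < alpha
        final_tests = trace.groupby("dropped").last()
        for t in fit.terms:
            assert final_tests.loc[t, "p"] <= 0.05
    assert removed >= 18
    assert kept_real >= 18


def test_boundary_rates_require_squeeze():
    data = _landscape_data(12).copy()
    data.loc[data.index[0], "rate_per_km"] = 1.0
    with pytest.raises(ValueError, match="squeeze"):
        st.fit_rate_landscape(data, candidates=("grassland",), squeeze="off", select=False)
    # the auto squeeze handles it
    fit, _ = st.fit_rate_landscape(data, candidates=("grassland",), select=False)
    assert np.isfinite(fit.loglik)


def test_marginal_effects_flat_for_zero_slope_and_roundtrip():
    rng = np.random.default_rng(13)
    x = rng.uniform(0, 1, 200)
    z = rng.uniform(0, 1, 200)
    mu = expit(0.5 + 1.5 * z)  # x truly has no effect
    y = rng.beta(mu * 500, (1 - mu) * 500)
    data = pd.DataFrame({"rate_per_km": y, "x": x, "z": z})
    fit, _ = st.fit_rate_landscape(data, candidates=("x", "z"), select=False)
    me = st.marginal_effects(fit, "x")
    assert np.ptp(me["success_std"]) < 0.05
    # fitted-value identity at the observed rows
    res = fit.extra["results"]
    from smoltrak.inference import build_design
    X, names = build_design(data, fit.terms)
    eta = X @ fit.params.to_numpy()
    assert np.allclose(expit(eta), res.predict(), atol=1e-8)
    with pytest.warns(UserWarning, match="observed range"):
        st.marginal_effects(fit, "x", grid=np.linspace(-1, 2, 5))


def test_bedrock_pairwise_contrast_structure():
    data = _landscape_data(14)
    fit, _ = st.fit_rate_landscape(
        data, candidates=("grassland", "woodland", "wetland", "peat", "bedrock"), select=False)
    pw = st.bedrock_pairwise(fit)
    assert len(pw) == 3
    dfree = fit.n - fit.df_model
    for _, row in pw.iterrows():
        unadj = 2 * stats.t.sf(abs(row["t"]), dfree)
        assert row["p_tukey"] >= unadj - 1e-12  # adjustment only inflates p
    # generator: igneous baseline far above metamorphic; that contrast is strong
    assert pw.set_index("contrast").loc["igneous - metamorphic", "p_tukey"] < 0.01


def test_bedrock_level_absent_reported_inestimable():
    data = _landscape_data(15)
    data = data[data["bedrock"] != "sedimentary"]
    fit, _ = st.fit_rate_landscape(data, candidates=("grassland", "bedrock"), select=False)
    pw = st.bedrock_pairwise(fit)
    missing = pw[~pw["estimable"]]
    assert len(missing) == 2  # both contrasts involving the absent level
    assert missing["p_tukey"].isna().all()


def test_kfold_check_flags_no_overfit_for_true_model():
    rng = np.random.default_rng(21)
    n = 150
    g = rng.uniform(0, 0.6, n)
    mu = expit(1.5 - 2.0 * g)
    data = pd.DataFrame({"rate_per_km": rng.beta(mu * 300, (1 - mu) * 300), "grassland": g})
    out = st.kfold_check(data, ("grassland",))
    # well-specified model: held-out error close to in-sample error
    assert out["ratio"] < 1.5
    assert out["mae_out_of_sample"] < 0.05


# ----------------------------------------------- exceedance mixed model

def _exceedance_data(seed, slope=0.0, n_rivers=13, n_years=3):
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_rivers):
        ur = rng.normal(0, 0.4)
        for y in range(n_years):
            x = rng.uniform(20, 80)
            mu = expit(2.5 + slope * (x - 50) + ur)
            rows.append({"river": f"R{r:02d}", "year": 2019 + y, "exceedance": x,
                         "rate_per_km": rng.beta(mu * 200, (1 - mu) * 200)})
    return pd.DataFrame(rows)


def test_exceedance_null_rejection_rate_near_alpha():
    rejections = []
    for seed in range(40):
        _, test = st.fit_rate_exceedance(_exceedance_data(seed))
        rejections.append(test.p < 0.05)
    rate = np.mean(rejections)
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40)


def test_exceedance_strong_effect_detected():
    hits = sum(st.fit_rate_exceedance(_exceedance_data(100 + s, slope=-0.04))[1].p < 0.05
               for s in range(10))
    assert hits >= 9


def test_exceedance_single_river_falls_back_to_fixed():
    data = _exceedance_data(3).query("river == 'R00'")
    with pytest.warns(UserWarning, match="single river"):
        fit, test = st.fit_rate_exceedance(data)
    assert "exceedance" in fit.terms


def test_lrt_pvalues_uniform_under_null_beta_glm():
    # fixed-effect beta regression: null-covariate LRT p-values ~ U(0,1)
    rng = np.random.default_rng(17)
    pvals = []
    for _ in range(200):
        x = rng.uniform(size=40)
        mu = 0.9
        y = rng.beta(mu * 100, (1 - mu) * 100, size=40)
        d = pd.DataFrame({"rate_per_km": y, "x": x})
        full = _fit_beta_glm(d, ("x",), "rate_per_km")
        null = _fit_beta_glm(d, (), "rate_per_km")
        pvals.append(st.lrt(null, full).p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
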