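"""Varying-coefficient Poisson GAMM: design bookkeeping, recovery, scenarios."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from beetlephen.gamm import (
    GammSpec,
    build_design,
    fit_gamm,
    partial_effect_cdd,
    predict_scenario,
)

from conftest import TWO_HUMP, sim_vc_data, two_hump_curve


@pytest.fixture(scope="module")
def fitted():
    df = sim_vc_data(seed=11)
    design = build_design(df, GammSpec(covariates=("v1", "v2")))
    return df, design, fit_gamm(design)


# ---- design construction --------------------------------------------------

def test_design_dimension_bookkeeping():
    df = sim_vc_data(seed=0, n_sites=20, years=(2020, 2021), obs_per_site_year=3)
    d0 = build_design(df, GammSpec(covariates=()))
    # intercept + year + (k_cdd - 1) smooth columns + site block
    assert d0.X.shape[1] == 1 + 1 + 8 + 20
    d1 = build_design(df, GammSpec(covariates=("v1",), k_interaction=10))
    # adds 1 linear column + (10 - 1) constrained interaction columns
    assert d1.X.shape[1] == d0.X.shape[1] + 1 + 9


def test_design_interaction_columns_vanish_at_zero_covariate():
    df = sim_vc_data(seed=1, n_sites=10, years=(2020,), obs_per_site_year=3)
    df["v1"] = 0.0
    d = build_design(df, GammSpec(covariates=("v1",)))
    sm = next(s for s in d.smooths if s.by == "v1")
    assert np.allclose(d.X[:, sm.cols], 0.0)


def test_design_missing_covariate_errors():
    df = sim_vc_data(seed=1, n_sites=5, years=(2020,))
    with pytest.raises(KeyError, match="bogus"):
        build_design(df, GammSpec(covariates=("bogus",)))


def test_basis_dimension_floor():
    with pytest.raises(ValueError):
        GammSpec(k_cdd=2)


# ---- fitting --------------------------------------------------------------

def test_fit_rejects_bad_responses():
    df = sim_vc_data(seed=2, n_sites=5, years=(2020,))
    d = build_design(df, GammSpec(covariates=()))
    d.y = d.y + 0.5
    with pytest.raises(ValueError, match="integer"):
        fit_gamm(d)
    d.y = np.zeros_like(d.y)
    with pytest.raises(ValueError, match="zero"):
        fit_gamm(d)


def test_intercept_only_constant_mean():
    rng = np.random.default_rng(3)
    mu = 5.0
    df = pd.DataFrame({
        "site_id": "s0", "year": 2020,
        "cdd": rng.uniform(100, 2000, 400),
        "count": rng.poisson(mu, 400),
    })
    d = build_design(df, GammSpec(covariates=(), year_term=False, site_random_effect=False))
    fit = fit_gamm(d)
    est = fit.parametric_table.set_index("term").loc["intercept", "estimate"]
    assert est == pytest.approx(np.log(mu), abs=0.1)
    # the CDD smooth should shrink toward nothing
    assert fit.smooth_table["edf"].iloc[0] < 3.0


def test_parameter_recovery_single_fit(fitted):
    _, _, fit = fitted
    pt = fit.parametric_table.set_index("term")
    assert abs(pt.loc["year", "estimate"] - 0.1) < 3 * pt.loc["year", "se"]
    assert abs(pt.loc["v1", "estimate"] - 0.3) < 3 * pt.loc["v1", "se"]
    assert abs(pt.loc["v2", "estimate"] + 0.2) < 3 * pt.loc["v2", "se"]
    assert 0.15 < fit.site_sd < 0.5  # true 0.3


def test_edf_bounded_by_reference(fitted):
    _, _, fit = fitted
    assert ((fit.smooth_table["edf"] > 0) & (fit.smooth_table["edf"] <= fit.smooth_table["ref_df"] + 1e-6)).all()


def test_null_interactions_shrink(fitted):
    _, _, fit = fitted
    st = fit.smooth_table.set_index("term")
    # v1 and v2 were simulated with constant coefficients: f_v == 0
    assert st.loc["s(cdd):v1", "edf"] < 3.0
    assert st.loc["s(cdd):v2", "edf"] < 3.0


def test_matches_mgcv_reml_fit(fitted, tmp_path):
    """Independent oracle: mgcv's REML Poisson GAMM on the same data.

    Bases differ (cr vs P-splines) and mgcv's uncentred by-smooths absorb
    the linear covariate terms, so agreement is checked on the year trend,
    the random-intercept SD, and the fitted linear predictor — quantities
    both parameterizations define identically.
    """
    df, design, fit = fitted
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    eta_py = design.X @ fit.beta
    np.savetxt(tmp_path / "eta.txt", eta_py)
    r_code = f"""
    suppressMessages(library(mgcv))
    d <- read.csv('{csv}')
    d$site_id <- factor(d$site_id)
    d$year_c <- d$year - mean(d$year)
    m <- gam(count ~ year_c + s(cdd, k=9) + s(cdd, by=v1, k=10) +
                 s(cdd, by=v2, k=10) + s(site_id, bs='re'),
             family=poisson, method='REML', data=d)
    p <- summary(m)$p.table
    vc <- gam.vcomp(m)
    eta <- predict(m, type='link')
    py <- scan('{tmp_path / "eta.txt"}', quiet=TRUE)
    cat(p['year_c','Estimate'], p['year_c','Std. Error'],
        vc['s(site_id)','std.dev'], sqrt(mean((eta - py)^2)), sep='\\n')
    """
    out = subprocess.run(
        ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
    )
    year_r, year_se_r, site_sd_r, rmse = map(float, out.stdout.strip().split("\n")[-4:])
    pt = fit.parametric_table.set_index("term")
    assert pt.loc["year", "estimate"] == pytest.approx(year_r, abs=3 * year_se_r)
    assert pt.loc["year", "se"] == pytest.approx(year_se_r, rel=0.25)
    assert fit.site_sd == pytest.approx(site_sd_r, rel=0.15)
    assert rmse < 0.15


# ---- partial effects ------------------------------------------------------

def test_partial_effect_recovers_two_humps(fitted):
    _, _, fit = fitted
    grid = np.linspace(160, 2150, 400)
    pe = partial_effect_cdd(fit, grid)
    assert np.all(pe.lo <= pe.effect) and np.all(pe.effect <= pe.hi)
    # local maxima near the true hump locations
    from scipy.signal import argrelmax

    pk = grid[argrelmax(pe.effect, order=10)[0]]
    assert min(abs(pk - TWO_HUMP["c1"])) < 50
    assert min(abs(pk - TWO_HUMP["c2"])) < 50


def test_partial_effect_null_smooth_ci_covers_zero():
    df = sim_vc_data(seed=21, n_sites=60, years=(2020, 2021), phenology=False)
    fit = fit_gamm(build_design(df, GammSpec(covariates=("v1", "v2"))))
    pe = partial_effect_cdd(fit, np.linspace(200, 2100, 200))
    assert np.mean((pe.lo <= 0) & (0 <= pe.hi)) >= 0.9


def test_partial_effect_ci_shrinks_with_n():
    widths = []
    for n_sites in (40, 160):
        df = sim_vc_data(seed=22, n_sites=n_sites, years=(2020, 2021))
        fit = fit_gamm(build_design(df, GammSpec(covariates=())))
        pe = partial_effect_cdd(fit, np.linspace(300, 2000, 100))
        widths.append(np.mean(pe.hi - pe.lo))
    assert widths[1] < widths[0]


def test_partial_effect_extrapolation_error(fitted):
    _, _, fit = fitted
    with pytest.raises(ValueError, match="range"):
        partial_effect_cdd(fit, np.array([0.0, 5000.0]))


# ---- scenarios ------------------------------------------------------------

def test_scenario_positive_beta_orders_curves(fitted):
    _, _, fit = fitted
    grid = np.linspace(200, 2100, 80)
    p10, p50, p90 = predict_scenario(
        fit, "v1", {10: -1.2816, 50: 0.0, 90: 1.2816}, grid
    )
    assert np.all(p90.mean >= p10.mean)  # beta_v1 = +0.3, f identically 0
    assert np.all(p50.mean > 0)


def test_scenario_mean_percentile_equals_all_means_prediction(fitted):
    _, _, fit = fitted
    grid = np.linspace(200, 2100, 50)
    (sc,) = predict_scenario(fit, "v1", {50: 0.0}, grid)
    per_year = [
        np.exp(fit.design.prediction_row(grid, year=yr) @ fit.beta)
        for yr in fit.design.years
    ]
    assert np.allclose(sc.mean, np.mean(per_year, axis=0), rtol=1e-12)


def test_scenario_null_focal_curves_within_ci(fitted):
    df = sim_vc_data(seed=23, betas=(0.0, -0.2))
    fit = fit_gamm(build_design(df, GammSpec(covariates=("v1", "v2"))))
    grid = np.linspace(200, 2100, 60)
    p10, p90 = predict_scenario(fit, "v1", {10: -1.2816, 90: 1.2816}, grid)
    half_width = (p90.hi - p90.lo) / 2
    assert np.all(np.abs(p90.mean - p10.mean) < half_width)


def test_scenario_no_year_trend_gives_identical_yearly_curves():
    df = sim_vc_data(seed=24, n_sites=40, years=(2020, 2021, 2022), gamma=0.0)
    fit = fit_gamm(build_design(df, GammSpec(covariates=("v1",))))
    grid = np.linspace(300, 2000, 40)
    rows = [fit.design.prediction_row(grid, year=yr) for yr in fit.design.years]
    etas = np.stack([r @ fit.beta for r in rows])
    assert np.ptp(etas, axis=0).max() < 0.05  # gamma-hat ~ 0


def test_scenario_unknown_focal_errors(fitted):
    _, _, fit = fitted
    with pytest.raises(KeyError):
        predict_scenario(fit, "nope", {50: 0.0}, np.linspace(300, 2000, 10))
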