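"""Varying-coefficient Poisson GAMM and percentile scenario predictions.

The abundance model for one life stage is a penalized Poisson regression
(log link)

    log E[count] = beta0 + gamma * (year - mean year)
                   + sum_v [beta_v * v + f_v(CDD) * v]
                   + f0(CDD) + b_site,

where each covariate v (a normalized site-year feature) enters both as a
linear parametric term and through a smooth varying coefficient f_v(CDD)
(cubic B-spline basis, sum-to-zero constrained, second-order difference
penalty), f0 is the main CDD smooth, and b_site are site random intercepts
realized as an identity-penalized ridge block.  Smoothing parameters —
one per smooth plus one for the site block — are chosen by maximizing the
Laplace-approximate restricted marginal likelihood (REML); effective
degrees of freedom, Wald tests and Bayesian credible/confidence intervals
come from the penalized information matrix at the optimum.

Basis dimensions default to 9 for the CDD smooth and 10 for each
interaction smooth; after the sum-to-zero constraint these give reference
degrees of freedom 8 and 9.

Scenario prediction: hold every covariate at its normalized mean (0), the
site effect at its zero mode, set the focal covariate to a chosen
percentile of its raw range (converted to the normalized scale), predict
the response-scale curve over a CDD grid for each sampling year, and
average the curves across years.  The band is the 95% interval of the
year-averaged linear predictor, exponentiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

from ._penalized import pirls_poisson, poisson_loglik

__all__ = [
    "GammSpec",
    "GammDesign",
    "FittedGamm",
    "PartialEffect",
    "ScenarioPrediction",
    "build_design",
    "fit_gamm",
    "partial_effect_cdd",
    "predict_scenario",
]


@dataclass
class GammSpec:
    """Model structure for one life stage."""

    life_stage: str = "consumer"
    covariates: tuple[str, ...] = ()
    k_cdd: int = 9           # basis dimension of the CDD main smooth
    k_interaction: int = 10  # basis dimension of each CDD-by-covariate smooth
    site_random_effect: bool = True
    year_term: bool = True

    def __post_init__(self):
        if self.k_cdd < 3 or self.k_interaction < 3:
            raise ValueError("basis dimensions must be >= 3")


@dataclass
class _SmoothBlock:
    name: str
    cols: slice
    knots: np.ndarray
    degree: int
    Z: np.ndarray          # sum-to-zero constraint transform (k, k-1)
    S: np.ndarray          # constrained penalty matrix
    by: str | None         # varying-coefficient covariate, None for the main smooth
    ref_df: int


def _bspline_matrix(x, knots, degree=3):
    x = np.clip(np.asarray(x, dtype=float), knots[degree], knots[-degree - 1])
    return BSpline.design_matrix(x, knots, degree).toarray()


def _make_basis(x, k, degree=3):
    lo, hi = float(np.min(x)), float(np.max(x))
    interior = np.linspace(lo, hi, k - degree + 1)
    knots = np.concatenate([[lo] * degree, interior, [hi] * degree])
    B = _bspline_matrix(x, knots, degree)
    # second-order difference penalty on the spline coefficients
    D = np.diff(np.eye(k), n=2, axis=0)
    S_full = D.T @ D
    # sum-to-zero over the observed data: null-space transform of colmeans
    c = B.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(c)
    Z = vt[1:].T
    return B @ Z, knots, Z, Z.T @ S_full @ Z


@dataclass
class GammDesign:
    X: np.ndarray
    y: np.ndarray
    spec: GammSpec
    parametric: list[tuple[str, int]]      # (name, column)
    smooths: list[_SmoothBlock]
    site_cols: slice | None
    site_levels: list
    year_mean: float
    years: tuple[int, ...]
    cdd_range: tuple[float, float]

    @property
    def n_lambda(self) -> int:
        return len(self.smooths) + (1 if self.site_cols is not None else 0)

    def penalty(self, lam: np.ndarray) -> np.ndarray:
        p = self.X.shape[1]
        S = np.zeros((p, p))
        for j, sm in enumerate(self.smooths):
            S[sm.cols, sm.cols] += lam[j] * sm.S
        if self.site_cols is not None:
            idx = np.arange(p)[self.site_cols]
            S[idx, idx] += lam[len(self.smooths)]
        return S

    def prediction_row(self, cdd, year=None, covariate_values: dict | None = None):
        """Design rows for arbitrary (CDD, year, covariates); site effect 0."""
        cdd = np.atleast_1d(np.asarray(cdd, dtype=float))
        vals = covariate_values or {}
        X = np.zeros((len(cdd), self.X.shape[1]))
        for name, col in self.parametric:
            if name == "intercept":
                X[:, col] = 1.0
            elif name == "year":
                X[:, col] = 0.0 if year is None else year - self.year_mean
            else:
                X[:, col] = vals.get(name, 0.0)
        for sm in self.smooths:
            B = _bspline_matrix(cdd, sm.knots, sm.degree) @ sm.Z
            if sm.by is None:
                X[:, sm.cols] = B
            else:
                X[:, sm.cols] = B * vals.get(sm.by, 0.0)
        return X


def build_design(data: pd.DataFrame, spec: GammSpec) -> GammDesign:
    """Assemble the penalized design from per-observation data.

    ``data`` needs columns: count (the response), cdd, year, site_id, and
    one normalized column per covariate in the spec.
    """
    missing = [c for c in spec.covariates if c not in data.columns]
    if missing:
        raise KeyError(f"covariates missing from data: {missing}")
    n = len(data)
    y = data["count"].to_numpy(dtype=float)
    cdd = data["cdd"].to_numpy(dtype=float)
    cols: list[np.ndarray] = []
    parametric = []
    pos = 0

    def push(block, name=None):
        nonlocal pos
        cols.append(np.atleast_2d(block.T).T if block.ndim == 1 else block)
        width = 1 if block.ndim == 1 else block.shape[1]
        if name is not None:
            parametric.append((name, pos))
        start = pos
        pos += width
        return slice(start, pos)

    push(np.ones(n), "intercept")
    year_mean = float(data["year"].mean())
    if spec.year_term:
        push(data["year"].to_numpy(dtype=float) - year_mean, "year")
    for v in spec.covariates:
        push(data[v].to_numpy(dtype=float), v)

    smooths = []
    B0, knots0, Z0, S0 = _make_basis(cdd, spec.k_cdd)
    sl = push(B0)
    smooths.append(_SmoothBlock("s(cdd)", sl, knots0, 3, Z0, S0, None, spec.k_cdd - 1))
    for v in spec.covariates:
        B, knots, Z, S = _make_basis(cdd, spec.k_interaction)
        sl = push(B * data[v].to_numpy(dtype=float)[:, None])
        smooths.append(
            _SmoothBlock(f"s(cdd):{v}", sl, knots, 3, Z, S, v, spec.k_interaction - 1)
        )

    site_cols = None
    site_levels: list = []
    if spec.site_random_effect:
        codes, site_levels = pd.factorize(data["site_id"])
        Bs = np.zeros((n, len(site_levels)))
        Bs[np.arange(n), codes] = 1.0
        site_cols = push(Bs)
        site_levels = list(site_levels)

    X = np.hstack(cols)
    return GammDesign(
        X=X, y=y, spec=spec, parametric=parametric, smooths=smooths,
        site_cols=site_cols, site_levels=site_levels, year_mean=year_mean,
        years=tuple(sorted(pd.unique(data["year"]).astype(int))),
        cdd_range=(float(cdd.min()), float(cdd.max())),
    )


@dataclass
class FittedGamm:
    design: GammDesign
    beta: np.ndarray
    Vb: np.ndarray           # Bayesian covariance of the coefficients
    lambdas: np.ndarray
    parametric_table: pd.DataFrame
    smooth_table: pd.DataFrame
    site_sd: float
    edf_total: float
    deviance_explained: float
    pseudo_r2: float
    criterion: str = "REML"
    laml: float = float("nan")

    def predict_eta(self, X: np.ndarray):
        eta = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.Vb, X), 0.0))
        return eta, se


def _laml(design: GammDesign, rho, state) -> float:
    """Negative Laplace-approximate REML at log smoothing parameters rho."""
    lam = np.exp(rho)
    S = design.penalty(lam)
    try:
        beta, eta, mu, XtWX, _ = pirls_poisson(design.X, design.y, S, beta0=state.get("beta"))
    except RuntimeError:
        return 1e10
    state["beta"] = beta
    ll = poisson_loglik(design.y, mu) - 0.5 * beta @ S @ beta
    # log |S|_+ decomposes over non-overlapping blocks
    logdet_S = 0.0
    for j, sm in enumerate(design.smooths):
        logdet_S += sm.rank * rho[j] + sm.logdet_pos
    if design.site_cols is not None:
        n_site = len(design.site_levels)
        logdet_S += n_site * rho[len(design.smooths)]
    H = XtWX + S
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return 1e10
    return -(ll + 0.5 * logdet_S - 0.5 * logdet_H)


def _prepare_penalty_spectra(design: GammDesign) -> None:
    for sm in design.smooths:
        eig = np.linalg.eigvalsh(sm.S)
        pos = eig[eig > eig.max() * 1e-10]
        sm.rank = len(pos)
        sm.logdet_pos = float(np.sum(np.log(pos)))


def fit_gamm(design: GammDesign, max_outer: int = 80) -> FittedGamm:
    """Fit by penalized IRLS with REML-selected smoothing parameters."""
    if design.y.min() < 0 or not np.allclose(design.y, np.round(design.y)):
        raise ValueError("response must be non-negative integer counts")
    if design.y.sum() == 0:
        raise ValueError("all-zero response; degenerate fit")
    _prepare_penalty_spectra(design)
    state: dict = {}
    rho0 = np.zeros(design.n_lambda)
    res = optimize.minimize(
        lambda r: _laml(design, r, state), rho0, method="L-BFGS-B",
        bounds=[(-10.0, 18.0)] * design.n_lambda,
        options={"maxiter": max_outer, "ftol": 1e-9},
    )
    lam = np.exp(res.x)
    S = design.penalty(lam)
    beta, eta, mu, XtWX, _ = pirls_poisson(design.X, design.y, S, beta0=state.get("beta"))
    p = design.X.shape[1]
    H = XtWX + S
    Vb = np.linalg.inv(H + 1e-10 * np.eye(p))
    F = Vb @ XtWX  # EDF matrix
    edf = np.diag(F)

    rows = []
    for name, col in design.parametric:
        se = float(np.sqrt(Vb[col, col]))
        z = beta[col] / se if se > 0 else np.inf
        rows.append({
            "term": name, "estimate": float(beta[col]), "se": se,
            "z": float(z), "p_value": float(2 * stats.norm.sf(abs(z))),
        })
    parametric_table = pd.DataFrame(rows)

    srows = []
    for j, sm in enumerate(design.smooths):
        e = float(edf[sm.cols].sum())
        b = beta[sm.cols]
        Vj = Vb[sm.cols, sm.cols]
        r = max(1, min(int(np.ceil(e)), b.size))
        # rank-r Wald statistic on the smooth coefficients
        evals, evecs = np.linalg.eigh(Vj)
        order = np.argsort(evals)[::-1][:r]
        T = float(np.sum((evecs[:, order].T @ b) ** 2 / evals[order]))
        srows.append({
            "term": sm.name, "edf": e, "ref_df": sm.ref_df,
            "lambda": float(lam[j]), "chi_sq": T,
            "p_value": float(stats.chi2.sf(T, r)),
        })
    smooth_table = pd.DataFrame(srows)

    site_sd = 0.0
    if design.site_cols is not None:
        site_sd = float(1.0 / np.sqrt(lam[len(design.smooths)]))

    y = design.y
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        mu0 = y.mean()
        dev0 = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu0), 0.0) - (y - mu0))
    edf_total = float(edf.sum())
    n = len(y)
    dev_expl = float(1.0 - dev / dev0)
    r2 = float(1.0 - (dev / max(n - edf_total, 1)) / (dev0 / (n - 1)))
    return FittedGamm(
        design=design, beta=beta, Vb=Vb, lambdas=lam,
        parametric_table=parametric_table, smooth_table=smooth_table,
        site_sd=site_sd, edf_total=edf_total,
        deviance_explained=dev_expl, pseudo_r2=r2, laml=float(-res.fun),
    )


@dataclass
class PartialEffect:
    grid: np.ndarray
    effect: np.ndarray   # link scale, centred
    lo: np.ndarray
    hi: np.ndarray


def partial_effect_cdd(fit: FittedGamm, grid) -> PartialEffect:
    """Link-scale CDD main smooth with pointwise 95% CI, all else at mean."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = fit.design.cdd_range
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError(f"grid outside fitted CDD range [{lo:.1f}, {hi:.1f}]")
    sm = fit.design.smooths[0]
    B = _bspline_matrix(grid, sm.knots, sm.degree) @ sm.Z
    b = fit.beta[sm.cols]
    V = fit.Vb[sm.cols, sm.cols]
    eff = B @ b
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
    return PartialEffect(grid=grid, effect=eff, lo=eff - 1.96 * se, hi=eff + 1.96 * se)


@dataclass
class ScenarioPrediction:
    focal: str
    percentile: int
    grid: np.ndarray
    mean: np.ndarray   # response scale, averaged over years
    lo: np.ndarray
    hi: np.ndarray


def predict_scenario(
    fit: FittedGamm,
    focal: str,
    values_by_percentile: dict[int, float],
    grid,
    years: tuple[int, ...] | None = None,
) -> list[ScenarioPrediction]:
    """Percentile scenario curves for one focal covariate.

    ``values_by_percentile`` maps each percentile to the focal covariate's
    value on the *normalized* scale.  All other covariates sit at 0 (their
    normalized mean), the site effect at its zero mode.  Curves are
    predicted per sampling year on the response scale and averaged; the CI
    comes from the year-averaged linear predictor.
    """
    if focal not in fit.design.spec.covariates:
        raise KeyError(f"{focal!r} is not a model covariate")
    years = years or fit.design.years
    grid = np.asarray(grid, dtype=float)
    out = []
    for pct, val in values_by_percentile.items():
        Xy = [
            fit.design.prediction_row(grid, year=yr, covariate_values={focal: val})
            for yr in years
        ]
        curves = np.stack([np.exp(np.clip(X @ fit.beta, -30, 30)) for X in Xy])
        Xbar = np.mean(Xy, axis=0)
        eta_bar, se = fit.predict_eta(Xbar)
        out.append(
            ScenarioPrediction(
                focal=focal, percentile=int(pct), grid=grid,
                mean=curves.mean(axis=0),
                lo=np.exp(eta_bar - 1.96 * se), hi=np.exp(eta_bar + 1.96 * se),
            )
        )
    return out
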