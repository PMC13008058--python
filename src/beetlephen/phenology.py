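"""Phenology landmarks and generation periods on the cumulative degree-day axis.

The season is segmented from count data in three steps.  First a Poisson
log-link regression of counts on nuisance fixed effects (year) plus one
coefficient per CDD bin is fitted, with ridge shrinkage on the bin block
(bins act like levels of a random effect, shrunk toward the seasonal mean;
the ridge strength is picked by generalized cross-validation).  The bin
coefficients, centred to mean zero, trace relative log-abundance across the
season.  Second, a smoothing spline is drawn through (bin centre,
coefficient).  Third, landmarks are read off the smooth curve: the first
negative-to-positive crossing is the start of colonization, local maxima
are generation emergence peaks, the minima between consecutive peaks are
generation breakpoints, and the last positive-to-negative crossing ends the
season.  The landmarks then cut the CDD axis into half-open seasonal
periods (winter/spring before colonization, one interval per generation,
fall/winter after).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline, make_smoothing_spline
from scipy.signal import argrelmin, find_peaks

from ._penalized import pirls_poisson

__all__ = [
    "PhenologyCurve",
    "PhenologyEvents",
    "GenerationPeriods",
    "fit_cdd_profile",
    "detect_events",
    "build_periods",
    "NoEventsError",
    "InsufficientEventsError",
    "DegenerateFitError",
]


class NoEventsError(ValueError):
    """The smooth curve never rises above zero; no landmarks exist."""


class InsufficientEventsError(ValueError):
    """Fewer peaks detected than generations requested."""


class DegenerateFitError(ValueError):
    """Counts carry no usable signal (e.g. all zero)."""


@dataclass
class PhenologyCurve:
    cdd_bin_centers: np.ndarray
    bin_coefficients: np.ndarray
    grid: np.ndarray
    smooth: np.ndarray
    ridge_lambda: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cdd": self.grid, "smooth": self.smooth})


@dataclass
class PhenologyEvents:
    colonization_cdd: float
    peak_cdds: list[float]
    breakpoint_cdds: list[float]
    season_end_cdd: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenerationPeriods:
    """Half-open partition of [0, inf) into labelled seasonal periods.

    ``boundaries`` are the interior cut points (colonization, then one per
    generation close); labels run winter_spring, gen1, ..., fall_winter.
    """

    boundaries: list[float]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if sorted(self.boundaries) != list(self.boundaries):
            raise ValueError("period boundaries must be non-decreasing")
        if not self.labels:
            n_gen = len(self.boundaries) - 1
            self.labels = (
                ["winter_spring"] + [f"gen{i+1}" for i in range(n_gen)] + ["fall_winter"]
            )

    def label_for(self, cdd) -> np.ndarray:
        cdd = np.asarray(cdd, dtype=float)
        if np.any(cdd < 0):
            raise ValueError("negative CDD")
        idx = np.searchsorted(self.boundaries, cdd, side="right")
        return np.asarray(self.labels, dtype=object)[idx]

    def intervals(self) -> list[tuple[str, float, float]]:
        edges = [0.0, *self.boundaries, np.inf]
        return [(lab, edges[i], edges[i + 1]) for i, lab in enumerate(self.labels)]

    def to_dict(self) -> dict:
        return {"boundaries": list(self.boundaries), "labels": list(self.labels)}


def fit_cdd_profile(
    counts: pd.DataFrame,
    dd: pd.DataFrame,
    life_stage: str = "adult",
    bin_width: float = 25.0,
    covariates: tuple[str, ...] = ("year",),
    ridge_grid: np.ndarray | None = None,
    grid_step: float = 5.0,
) -> PhenologyCurve:
    """Fit the binned-CDD Poisson profile and smooth it.

    ``counts`` is a CountObservationTable, ``dd`` a DegreeDaySeries; they
    are joined on site and date.  The ridge strength on the CDD-bin block
    is selected by GCV over ``ridge_grid`` (default 10^0..10^3).
    """
    obs = counts.loc[counts["life_stage"] == life_stage, ["site_id", "date", "count"]]
    obs = obs.merge(dd[["site_id", "date", "cdd"]], on=["site_id", "date"], how="inner")
    if obs.empty or obs["count"].sum() == 0:
        raise DegenerateFitError(f"no usable {life_stage} counts")

    y = obs["count"].to_numpy(dtype=float)
    n = len(y)
    bin_idx = np.floor(obs["cdd"].to_numpy() / bin_width).astype(int)
    n_bins = bin_idx.max() + 1
    centers = (np.arange(n_bins) + 0.5) * bin_width
    occupied = np.isin(np.arange(n_bins), bin_idx)
    if occupied.sum() < 2:
        raise DegenerateFitError("fewer than 2 non-empty CDD bins")
    if not occupied.all():
        warnings.warn(
            f"{(~occupied).sum()} empty CDD bins; their coefficients shrink to 0",
            stacklevel=2,
        )

    blocks = [np.ones((n, 1))]
    for cov in covariates:
        if cov == "year":
            vals = pd.to_datetime(obs["date"]).dt.year
        else:
            vals = obs[cov]
        dummies = pd.get_dummies(vals, drop_first=True, dtype=float)
        blocks.append(dummies.to_numpy())
    n_fixed = sum(b.shape[1] for b in blocks)
    B = np.zeros((n, n_bins))
    B[np.arange(n), bin_idx] = 1.0
    X = np.hstack([*blocks, B])
    p = X.shape[1]

    pen_mask = np.zeros(p)
    pen_mask[n_fixed:] = 1.0
    if ridge_grid is None:
        ridge_grid = np.logspace(0, 3, 7)

    best = None
    beta = None
    for lam in ridge_grid:
        S = np.diag(lam * pen_mask)
        beta, eta, mu, XtWX, _ = pirls_poisson(X, y, S, beta0=beta)
        # GCV on the working fit: n * deviance / (n - edf)^2
        A = XtWX + S
        edf = float(np.trace(np.linalg.solve(A, XtWX)))
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        gcv = n * dev / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta.copy())
    _, lam, beta = best

    coefs = beta[n_fixed:]
    coefs = coefs - coefs[occupied].mean()  # centre over informative bins
    coefs[~occupied] = 0.0

    x, c = centers[occupied], coefs[occupied]
    if len(x) >= 6:
        # Precision-weighted smoothing with the residual-consistent target
        # s = m.  A bin coefficient's variance is ~1/mass (Poisson) plus an
        # extra-Poisson component tau^2 from between-site/-year log-scale
        # heterogeneity; ignoring tau^2 lets high-mass bins pin the spline
        # and produce spurious wiggles.  tau^2 is method-of-moments from a
        # pilot fit's residuals.
        from scipy.interpolate import UnivariateSpline

        mass = np.bincount(bin_idx, weights=y, minlength=n_bins)[occupied] + 0.5
        m = float(len(x))
        pilot = UnivariateSpline(x, c, w=np.sqrt(mass), s=m, k=3)
        resid = c - pilot(x)
        tau2 = max(0.0, float(np.mean(resid**2 - 1.0 / mass)))
        w = 1.0 / np.sqrt(1.0 / mass + tau2)
        spl = UnivariateSpline(x, c, w=w, s=m, k=3)
    else:
        spl = make_interp_spline(x, c, k=min(3, len(x) - 1))
    grid = np.arange(0.0, centers[-1] + grid_step, grid_step)
    smooth = np.asarray(spl(np.clip(grid, x[0], x[-1])))
    return PhenologyCurve(
        cdd_bin_centers=centers, bin_coefficients=coefs, grid=grid,
        smooth=smooth, ridge_lambda=float(lam),
    )


def detect_events(curve, prominence_frac: float = 0.05) -> PhenologyEvents:
    """Read colonization, peaks, breakpoints, and season end off the curve.

    ``curve`` is a :class:`PhenologyCurve` or a ``(grid, values)`` pair.
    Peaks need prominence of at least ``prominence_frac`` of the curve range
    and a positive value.  Crossing locations are linearly interpolated.
    """
    if isinstance(curve, PhenologyCurve):
        grid, v = curve.grid, curve.smooth
    else:
        grid, v = (np.asarray(a, dtype=float) for a in curve)
    if v.max() <= 0:
        raise NoEventsError("curve never positive; no phenology events")

    prom = prominence_frac * (v.max() - v.min())
    pk, _ = find_peaks(v, prominence=prom)
    pk = pk[v[pk] > 0]
    if len(pk) == 0:  # positive plateau edge case: take the argmax
        pk = np.array([int(np.argmax(v))])

    def _cross(i):  # linear interpolation of the zero between i-1 and i
        x0, x1, y0, y1 = grid[i - 1], grid[i], v[i - 1], v[i]
        return float(x0 - y0 * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x1)

    up = np.flatnonzero((v[:-1] < 0) & (v[1:] >= 0)) + 1
    up = up[up <= pk[0]]
    colonization = _cross(up[-1]) if len(up) else float(grid[0])

    down = np.flatnonzero((v[:-1] > 0) & (v[1:] <= 0)) + 1
    down = down[down > pk[-1]]
    season_end = _cross(down[0]) if len(down) else float(grid[-1])

    breakpoints = []
    for a, b in zip(pk[:-1], pk[1:]):
        breakpoints.append(float(grid[a + int(np.argmin(v[a : b + 1]))]))
    return PhenologyEvents(
        colonization_cdd=colonization,
        peak_cdds=[float(grid[i]) for i in pk],
        breakpoint_cdds=breakpoints,
        season_end_cdd=season_end,
    )


def build_periods(events: PhenologyEvents, n_generations: int = 2) -> GenerationPeriods:
    """Cut the CDD axis into winter/spring, generation, and fall/winter periods.

    Generation g runs to the g-th breakpoint when one was detected;
    the last requested generation falls back to season end otherwise.
    Peaks beyond ``n_generations`` fold into the fall/winter period.
    """
    if len(events.peak_cdds) < n_generations:
        raise InsufficientEventsError(
            f"{len(events.peak_cdds)} peaks detected, {n_generations} generations requested"
        )
    bounds = [float(events.colonization_cdd)]
    for g in range(n_generations):
        if g < len(events.breakpoint_cdds):
            bounds.append(float(events.breakpoint_cdds[g]))
        else:
            bounds.append(float(events.season_end_cdd))
    return GenerationPeriods(boundaries=bounds)
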