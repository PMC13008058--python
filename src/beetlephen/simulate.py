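"""Synthetic sites, weather, land cover, and beetle counts with known truth.

Emulates a Wisconsin-like potato-growing region: weekly scouting of many
fields over several seasons, a two-generation (plus optional partial third)
beetle phenology driven by cumulative degree days (CDD, 11/31 °C single
sine), seasonal daily weather with realistic cross-correlations, and a
patchy categorical land-cover raster containing a focal potato class.

Counts are drawn from the generative model

    count ~ Poisson(lambda),
    log lambda = alpha_stage + phen_stage(CDD)
                 + sum_v [beta_v + f_v(CDD)] * v
                 + gamma * (year - year0) + b_site,

with b_site ~ N(0, sigma_site^2) fixed per site, and egg counts additionally
zeroed with probability pi (zero inflation).  The :class:`TruthRecord` used
to simulate is retained so downstream stages can be tested for recovery of
known landmarks and coefficients.

Stage phenology: adult abundance humps sit at the :class:`TruthRecord`
locations; larval humps are shifted +120 CDD later (the egg-to-first-instar
development time), egg humps +50 CDD (oviposition follows emergence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .degree_days import DegreeDayParams, cumulative_dd
from .landscape import CLASSES, LandscapeRaster, buffer_cells, class_area_ha

__all__ = ["Hump", "CovariateEffect", "TruthRecord", "SimConfig",
           "gen_sites", "gen_weather", "gen_landscape", "gen_counts",
           "simulate_all"]

_STAGE_SHIFT_CDD = {"adult": 0.0, "egg": 50.0, "larva": 120.0}
_STAGE_ALPHA_OFFSET = {"adult": 0.0, "larva": 0.4, "egg": -0.6}


@dataclass(frozen=True)
class Hump:
    """One generation's abundance hump on the CDD axis (Gaussian on log scale)."""

    center_cdd: float
    width_cdd: float = 140.0
    height: float = 2.4


@dataclass(frozen=True)
class CovariateEffect:
    """Effect of one site-year covariate: linear part plus optional CDD-varying part.

    ``f`` is None (constant coefficient) or a Gaussian-bump spec
    ``{"center": c, "width": w, "height": h}`` added to ``beta`` along CDD.
    ``name`` must be one of the built-in generative covariates
    (``potato_area``, ``season_tmax``, ``spring_precip``).
    """

    name: str
    beta: float
    f: dict | None = None

    def coef_at(self, cdd):
        out = np.full_like(np.asarray(cdd, dtype=float), self.beta)
        if self.f is not None:
            c, w, h = self.f["center"], self.f["width"], self.f["height"]
            out = out + h * np.exp(-0.5 * ((np.asarray(cdd, float) - c) / w) ** 2)
        return out


@dataclass(frozen=True)
class TruthRecord:
    """Generative parameters for the count model; kept for recovery tests.

    Defaults mirror the study system: adult humps near 500 and 1400 CDD
    (first/second generation emergence peaks), a mild positive year trend,
    moderate covariate effects, and between-field heterogeneity.
    """

    alpha: float = 0.3
    humps: tuple[Hump, ...] = (Hump(500.0, 200.0, 2.5), Hump(1400.0, 220.0, 2.1))
    covariate_effects: tuple[CovariateEffect, ...] = (
        CovariateEffect("potato_area", 0.25),
        CovariateEffect("season_tmax", 0.20),
        CovariateEffect("spring_precip", -0.10),
    )
    year_trend: float = 0.05
    sigma_site: float = 0.35

    def __post_init__(self):
        centers = [h.center_cdd for h in self.humps]
        if sorted(centers) != centers or len(set(centers)) != len(centers):
            raise ValueError("hump locations must be strictly increasing")
        if self.sigma_site < 0:
            raise ValueError("sigma_site must be >= 0")

    def phenology(self, cdd, stage: str = "adult"):
        """Log-scale phenology curve for one life stage at given CDD values."""
        shift = _STAGE_SHIFT_CDD[stage]
        cdd = np.asarray(cdd, dtype=float)
        out = np.zeros_like(cdd)
        for h in self.humps:
            out += h.height * np.exp(-0.5 * ((cdd - h.center_cdd - shift) / h.width_cdd) ** 2)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _default_mix() -> dict:
    # crop shares loosely matching a potato-rotation landscape
    return {
        "Potato": 0.10, "Corn": 0.22, "Soybean": 0.14, "Wheat": 0.04,
        "Legume": 0.04, "OtherCereals": 0.03, "Forage": 0.08, "OtherCrop": 0.05,
        "Water": 0.04, "Developed": 0.06, "SemiNatural": 0.20,
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic study region.

    Climate defaults produce a warm-temperate continental year whose season
    accumulates roughly 2000–2300 CDD (11/31 °C single sine) — enough for
    two full beetle generations and the tail of a third.
    """

    n_sites: int = 100
    years: tuple[int, ...] = (2019, 2020, 2021)
    extent_m: float = 12_000.0
    cell_size_m: float = 30.0
    seed: int = 0
    # climate
    mean_annual_t: float = 10.5       # °C
    seasonal_amplitude: float = 16.5  # °C, peak-to-mean
    ar1_coef: float = 0.7
    noise_sd: float = 3.0             # °C, regional AR(1) innovations
    site_noise_sd: float = 0.7        # °C, per-site daily jitter
    diurnal_range_mean: float = 10.0  # °C
    diurnal_range_sd: float = 2.0
    wet_day_prob: float = 0.30
    precip_shape: float = 0.6
    precip_scale_mm: float = 12.0
    # landscape
    class_mix: dict = field(default_factory=_default_mix)
    mean_patch_cells: int = 200
    # counts
    truth: TruthRecord = field(default_factory=TruthRecord)
    egg_zero_inflation: float = 0.5
    season_start_cdd: float = 150.0
    season_end_cdd: float = 2200.0
    buffer_radius_m: float = 1000.0

    def validate(self) -> list[str]:
        problems = []
        if self.n_sites < 1:
            problems.append("n_sites must be >= 1")
        if self.extent_m <= 2 * self.buffer_radius_m:
            problems.append(
                f"extent_m ({self.extent_m}) must exceed twice the buffer "
                f"radius ({self.buffer_radius_m}) so buffers fit"
            )
        if not 0.0 <= self.egg_zero_inflation <= 1.0:
            problems.append("egg_zero_inflation must be in [0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-6:
            problems.append("class_mix proportions must sum to 1")
        if any(k not in CLASSES for k in self.class_mix):
            problems.append("class_mix contains unknown class names")
        return problems

    def _check(self):
        problems = self.validate()
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def rng(self, component: int) -> np.random.Generator:
        # fixed per-component streams so each generator is deterministic
        # regardless of which others were called
        return np.random.default_rng(np.random.SeedSequence([self.seed, component]))


def gen_sites(cfg: SimConfig) -> pd.DataFrame:
    """Uniformly place fields, keeping a buffer-radius margin from the edge."""
    cfg._check()
    rng = cfg.rng(1)
    margin = cfg.buffer_radius_m
    lo, hi = margin, cfg.extent_m - margin
    xy = rng.uniform(lo, hi, size=(cfg.n_sites, 2))
    return pd.DataFrame(
        {"site_id": [f"site_{i:04d}" for i in range(cfg.n_sites)],
         "x": xy[:, 0], "y": xy[:, 1]}
    )


def _sat_vp_hpa(t_c):
    """Saturation vapour pressure (hPa), Tetens over water."""
    t_c = np.asarray(t_c, dtype=float)
    return 6.1078 * np.exp(17.27 * t_c / (t_c + 237.3))


def gen_weather(sites: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Daily weather per site: one regional series plus site-level noise.

    Mean temperature is a seasonal sinusoid (peak ~July 20) plus regional
    AR(1) noise; tmin/tmax bracket it by a random diurnal range.  VPD comes
    from the saturation-pressure curve at tmin/tmax minus a shared actual
    vapour pressure (wet days more humid), clipped at zero.  Precipitation
    is a regional Bernoulli wet-day indicator times a gamma amount with
    mild site-level scatter.  Snow-water equivalent accumulates precip on
    subfreezing days and melts instantly otherwise; soil temperature is a
    damped exponential smoothing of air temperature.
    """
    cfg._check()
    rng = cfg.rng(2)
    years = sorted(cfg.years)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    # keep only configured years (list may be non-contiguous)
    dates = dates[np.isin(dates.year, years)]
    nd = len(dates)
    doy = dates.dayofyear.to_numpy()

    seasonal = cfg.mean_annual_t - cfg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - 19) / 365.25
    )  # coldest ~Jan 19, warmest ~Jul 20
    innov = rng.normal(0.0, cfg.noise_sd, nd)
    ar = np.empty(nd)
    ar[0] = innov[0] / np.sqrt(1 - cfg.ar1_coef**2)
    for i in range(1, nd):
        ar[i] = cfg.ar1_coef * ar[i - 1] + innov[i]
    regional_tmean = seasonal + ar

    wet = rng.random(nd) < cfg.wet_day_prob
    amount = np.where(
        wet, rng.gamma(cfg.precip_shape, cfg.precip_scale_mm, nd), 0.0
    )
    rh = np.clip(rng.normal(0.70, 0.12, nd) + 0.10 * wet, 0.25, 1.0)

    n = len(sites)
    frames = []
    for idx, r in enumerate(sites.itertuples(index=False)):
        tmean = regional_tmean + rng.normal(0.0, cfg.site_noise_sd, nd)
        drange = np.clip(
            rng.normal(cfg.diurnal_range_mean, cfg.diurnal_range_sd, nd), 1.0, None
        )
        tmin = tmean - drange / 2
        tmax = tmean + drange / 2

        ea = rh * _sat_vp_hpa(tmean)
        vpdmin = np.clip(_sat_vp_hpa(tmin) - ea, 0.0, None)
        vpdmax = np.clip(_sat_vp_hpa(tmax) - ea, 0.0, None)

        precip = amount * np.where(wet, rng.lognormal(0.0, 0.15, nd), 1.0)

        swe = np.zeros(nd)
        pack = 0.0
        for i in range(nd):
            if tmax[i] < 0.0:
                pack += precip[i]
                swe[i] = pack
            else:
                pack = 0.0
        # daylight-average shortwave: winter trough ~100, summer peak ~400 W/m²
        srad = np.clip(
            250.0 - 150.0 * np.cos(2 * np.pi * (doy - 19) / 365.25)
            + rng.normal(0.0, 25.0, nd),
            10.0,
            None,
        )
        soil = np.empty(nd)
        prev = cfg.mean_annual_t
        for i in range(nd):
            target = 0.6 * tmean[i] + 0.4 * cfg.mean_annual_t
            prev = prev + 0.08 * (target - prev)
            soil[i] = prev
        frames.append(
            pd.DataFrame(
                {"site_id": r.site_id, "date": dates, "tmin": tmin, "tmax": tmax,
                 "precip": precip, "vpdmin": vpdmin, "vpdmax": vpdmax,
                 "srad": srad, "swe": swe, "soil_t": soil}
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_landscape(cfg: SimConfig) -> LandscapeRaster:
    """Patchy categorical raster by seeded nearest-seed region growing.

    Uniform random seeds (about one per ``mean_patch_cells`` cells) are
    assigned classes by largest remainder on the target mix; every cell
    joins its nearest seed's patch, giving contiguous patches whose realized
    class proportions approach the target within a few percentage points.
    """
    cfg._check()
    from scipy.spatial import cKDTree

    rng = cfg.rng(3)
    ncell = int(round(cfg.extent_m / cfg.cell_size_m))
    n_seeds = max(len(cfg.class_mix), (ncell * ncell) // cfg.mean_patch_cells)

    names = [c for c in CLASSES if cfg.class_mix.get(c, 0.0) > 0]
    props = np.array([cfg.class_mix[c] for c in names])
    counts = np.floor(props * n_seeds).astype(int)
    rem = props * n_seeds - counts
    for i in np.argsort(-rem)[: n_seeds - counts.sum()]:
        counts[i] += 1
    seed_classes = np.repeat([CLASSES.index(c) for c in names], counts)
    rng.shuffle(seed_classes)

    seeds = rng.uniform(0, ncell, size=(len(seed_classes), 2))
    rows, cols = np.mgrid[0:ncell, 0:ncell]
    pts = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, nearest = cKDTree(seeds).query(pts, workers=1)
    grid = np.asarray(seed_classes)[nearest].reshape(ncell, ncell).astype(np.int16)
    return LandscapeRaster(grid=grid, cell_size_m=cfg.cell_size_m, origin=(0.0, 0.0))


def generative_covariates(
    sites: pd.DataFrame,
    weather: pd.DataFrame,
    raster: LandscapeRaster | None,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Built-in site-year covariates the truth model may act on (z-scored).

    potato_area: potato hectares in the site's buffer (constant over years);
    season_tmax: median Jun–Aug tmax; spring_precip: Mar–May total precip.
    """
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w["year"] = w["date"].dt.year
    month = w["date"].dt.month
    tmax = (
        w[month.isin([6, 7, 8])].groupby(["site_id", "year"])["tmax"].median()
    ).rename("season_tmax")
    prc = (
        w[month.isin([3, 4, 5])].groupby(["site_id", "year"])["precip"].sum()
    ).rename("spring_precip")
    out = pd.concat([tmax, prc], axis=1).reset_index()
    if raster is not None:
        areas = {
            r.site_id: class_area_ha(
                buffer_cells(raster, (r.x, r.y), cfg.buffer_radius_m), raster, "Potato"
            )
            for r in sites.itertuples(index=False)
        }
        out["potato_area"] = out["site_id"].map(areas)
    else:
        out["potato_area"] = 0.0
    for col in ("potato_area", "season_tmax", "spring_precip"):
        sd = out[col].std(ddof=1)
        out[col] = 0.0 if (not np.isfinite(sd) or sd == 0) else (out[col] - out[col].mean()) / sd
    return out


def _sampling_dates(dd_site: pd.DataFrame, start_cdd: float, end_cdd: float):
    """Weekly scouting dates from CDD >= start to CDD >= end (or season end)."""
    dd_site = dd_site.sort_values("date")
    above = dd_site[dd_site["cdd"] >= start_cdd]
    if above.empty:
        return pd.DatetimeIndex([])
    first = above["date"].iloc[0]
    reached = dd_site[dd_site["cdd"] >= end_cdd]
    if reached.empty:
        accum = dd_site[dd_site["daily_dd"] > 0]
        last = accum["date"].iloc[-1] if not accum.empty else dd_site["date"].iloc[-1]
    else:
        last = reached["date"].iloc[0]
    return pd.date_range(first, last, freq="7D")


def gen_counts(
    sites: pd.DataFrame,
    weather: pd.DataFrame,
    raster: LandscapeRaster | None,
    truth: TruthRecord,
    cfg: SimConfig,
    dd: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Weekly life-stage counts from the known Poisson generative model.

    Returns a CountObservationTable (site_id, date, life_stage, count) with
    adult, larva, egg, and derived consumer (= adult + larva) rows.
    """
    cfg._check()
    rng = cfg.rng(4)
    if dd is None:
        dd = cumulative_dd(weather, DegreeDayParams())
    cov = generative_covariates(sites, weather, raster, cfg)
    known = {"potato_area", "season_tmax", "spring_precip"}
    for eff in truth.covariate_effects:
        if eff.name not in known:
            raise ValueError(f"truth references unknown covariate {eff.name!r}")

    site_ids = sites["site_id"].tolist()
    b_site = dict(zip(site_ids, rng.normal(0.0, truth.sigma_site, len(site_ids))))
    year0 = min(cfg.years)

    dd = dd.copy()
    dd["year"] = pd.to_datetime(dd["date"]).dt.year
    cov_idx = cov.set_index(["site_id", "year"])

    rows = []
    for (site, year), grp in dd.groupby(["site_id", "year"], sort=True):
        dates = _sampling_dates(grp, cfg.season_start_cdd, cfg.season_end_cdd)
        if len(dates) == 0:
            continue
        g = grp.set_index("date")["cdd"]
        cdd = g.reindex(dates).to_numpy()
        cv = cov_idx.loc[(site, year)]
        cov_term = np.zeros(len(dates))
        for eff in truth.covariate_effects:
            cov_term = cov_term + eff.coef_at(cdd) * float(cv[eff.name])
        base = (
            truth.alpha + cov_term + truth.year_trend * (year - year0) + b_site[site]
        )
        stage_counts = {}
        for stage in ("adult", "larva", "egg"):
            eta = base + _STAGE_ALPHA_OFFSET[stage] + truth.phenology(cdd, stage)
            counts = rng.poisson(np.exp(eta))
            if stage == "egg" and cfg.egg_zero_inflation > 0:
                counts = np.where(
                    rng.random(len(counts)) < cfg.egg_zero_inflation, 0, counts
                )
            stage_counts[stage] = counts
        stage_counts["consumer"] = stage_counts["adult"] + stage_counts["larva"]
        for stage in ("adult", "larva", "egg", "consumer"):
            rows.append(
                pd.DataFrame(
                    {"site_id": site, "date": dates, "life_stage": stage,
                     "count": stage_counts[stage]}
                )
            )
    if not rows:
        return pd.DataFrame(columns=["site_id", "date", "life_stage", "count"])
    return pd.concat(rows, ignore_index=True)


def simulate_all(cfg: SimConfig) -> dict:
    """Run every generator; returns sites, weather, landscape, dd, counts, truth."""
    sites = gen_sites(cfg)
    weather = gen_weather(sites, cfg)
    raster = gen_landscape(cfg)
    dd = cumulative_dd(weather, DegreeDayParams())
    counts = gen_counts(sites, weather, raster, cfg.truth, cfg, dd=dd)
    return {"sites": sites, "weather": weather, "landscape": raster,
            "dd": dd, "counts": counts, "truth": cfg.truth}
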