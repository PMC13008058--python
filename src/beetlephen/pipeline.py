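"""End-to-end orchestration: simulate → degree days → phenology → landscape
→ features → classify → GAMM → scenarios, from one declarative config.

Every stage reads its inputs from and writes its outputs to the run
directory, so stages can be re-run individually from persisted
intermediates.  A single master seed deterministically spawns per-stage
seeds; two runs with the same config produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import features as feat
from .degree_days import DegreeDayParams, cumulative_dd
from .gamm import GammSpec, build_design, fit_gamm, partial_effect_cdd, predict_scenario
from .landscape import buffer_metrics_table, read_ascii_grid, write_ascii_grid
from .phenology import build_periods, detect_events, fit_cdd_profile
from .simulate import SimConfig, TruthRecord, simulate_all

log = logging.getLogger("beetlephen")

__all__ = ["RunConfig", "validate_config", "run_all", "STAGES"]

TEMPORAL = ("cdd", "year")


@dataclass
class RunConfig:
    """All pipeline parameters with study defaults pre-filled."""

    outdir: str = "runs/default"
    seed: int = 1
    # synthetic region (problem size chosen to keep a full run desk-scale)
    n_sites: int = 60
    years: tuple[int, ...] = (2019, 2020, 2021)
    extent_m: float = 12_000.0
    cell_size_m: float = 30.0
    egg_zero_inflation: float = 0.5
    # degree days
    dd_lower: float = 11.0
    dd_upper: float = 31.0
    biofix: str = "01-01"
    # phenology
    bin_width: float = 25.0
    n_generations: int = 2
    phenology_stage: str = "adult"
    # landscape
    buffer_radius_m: float = 1000.0
    # features
    corr_threshold: float = 0.7
    # classifier
    classify_stages: tuple[str, ...] = ("consumer",)
    lower_pct: float = 25.0
    upper_pct: float = 75.0
    egg_lower_pct: float = 10.0
    egg_upper_pct: float = 90.0
    split_fraction: float = 0.75
    n_candidates: int = 30
    folds: int = 10
    n_perm: int = 50
    # gamm / scenarios
    top_k: int = 6
    percentiles: tuple[int, ...] = (10, 50, 90)
    k_cdd: int = 9
    k_interaction: int = 10
    scenario_grid_points: int = 80
    enabled: tuple[str, ...] = (
        "simulate", "degree_days", "phenology", "landscape",
        "features", "classify", "gamm",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("years", "classify_stages", "percentiles", "enabled"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_sites=self.n_sites, years=self.years, extent_m=self.extent_m,
            cell_size_m=self.cell_size_m, seed=self.stage_seed("simulate"),
            egg_zero_inflation=self.egg_zero_inflation,
            buffer_radius_m=self.buffer_radius_m,
        )

    def dd_params(self) -> DegreeDayParams:
        return DegreeDayParams(lower=self.dd_lower, upper=self.dd_upper, biofix=self.biofix)


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every parameter range; empty list iff the config is valid."""
    v = []
    if cfg.dd_lower >= cfg.dd_upper:
        v.append(f"dd_lower ({cfg.dd_lower}) must be below dd_upper ({cfg.dd_upper})")
    if not 0 < cfg.corr_threshold <= 1:
        v.append(f"corr_threshold ({cfg.corr_threshold}) must be in (0, 1]")
    if not 0 < cfg.split_fraction <= 1:
        v.append("split_fraction must be in (0, 1]")
    if not cfg.lower_pct < cfg.upper_pct:
        v.append("lower_pct must be below upper_pct")
    if cfg.bin_width <= 0:
        v.append("bin_width must be positive")
    if cfg.n_generations < 1:
        v.append("n_generations must be >= 1")
    if cfg.top_k < 1:
        v.append("top_k must be >= 1")
    if any(not 0 < p < 100 for p in cfg.percentiles):
        v.append("percentiles must be strictly between 0 and 100")
    unknown = set(cfg.enabled) - set(STAGES)
    if unknown:
        v.append(f"unknown stages enabled: {sorted(unknown)}")
    v.extend(cfg.sim_config().validate())
    return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


# ---- stages ---------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    out = simulate_all(cfg.sim_config())
    _write_csv(out["sites"], outdir / "sites.csv")
    _write_csv(out["weather"], outdir / "weather.csv")
    _write_csv(out["counts"], outdir / "counts.csv")
    write_ascii_grid(outdir / "landcover.asc", out["landscape"])
    out["truth"].to_json(outdir / "truth.json")
    return {"n_sites": cfg.n_sites, "n_count_rows": int(len(out["counts"]))}


def stage_degree_days(cfg: RunConfig, outdir: Path) -> dict:
    weather = pd.read_csv(outdir / "weather.csv", parse_dates=["date"])
    dd = cumulative_dd(weather, cfg.dd_params())
    _write_csv(dd, outdir / "degree_days.csv")
    return {"max_cdd": float(dd["cdd"].max())}


def stage_phenology(cfg: RunConfig, outdir: Path) -> dict:
    counts = pd.read_csv(outdir / "counts.csv", parse_dates=["date"])
    dd = pd.read_csv(outdir / "degree_days.csv", parse_dates=["date"])
    curve = fit_cdd_profile(counts, dd, cfg.phenology_stage, bin_width=cfg.bin_width)
    events = detect_events(curve)
    periods = build_periods(events, n_generations=cfg.n_generations)
    _write_csv(curve.to_frame(), outdir / "phenology_curve.csv")
    (outdir / "phenology_events.json").write_text(
        json.dumps({"events": events.to_dict(), "periods": periods.to_dict()}, indent=2)
    )
    return {"events": events.to_dict(), "boundaries": periods.boundaries}


def stage_landscape(cfg: RunConfig, outdir: Path) -> dict:
    raster = read_ascii_grid(outdir / "landcover.asc")
    sites = pd.read_csv(outdir / "sites.csv")
    metrics = buffer_metrics_table(raster, sites, radius_m=cfg.buffer_radius_m)
    _write_csv(metrics, outdir / "landscape_metrics.csv")
    return {"n_metrics": int(metrics.shape[1] - 1)}


def stage_features(cfg: RunConfig, outdir: Path) -> dict:
    from .phenology import GenerationPeriods

    weather = pd.read_csv(outdir / "weather.csv", parse_dates=["date"])
    dd = pd.read_csv(outdir / "degree_days.csv", parse_dates=["date"])
    pj = json.loads((outdir / "phenology_events.json").read_text())
    periods = GenerationPeriods(**pj["periods"])
    agg = feat.aggregate_period_weather(weather, dd, periods)
    lagged = feat.lag_fall_winter(agg)
    metrics = pd.read_csv(outdir / "landscape_metrics.csv")
    # drop all-missing metric columns (classes absent from every buffer)
    metrics = metrics.dropna(axis=1, how="all")
    full = lagged.merge(metrics, on="site_id", how="left")
    pruned, report = feat.prune_correlated(full, threshold=cfg.corr_threshold)
    _write_csv(full, outdir / "features_raw.csv")
    _write_csv(pruned, outdir / "features_pruned.csv")
    (outdir / "prune_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return {"n_raw": int(full.shape[1] - 2), "n_retained": len(report.retained)}


def _observation_table(cfg: RunConfig, outdir: Path, life_stage: str) -> pd.DataFrame:
    counts = pd.read_csv(outdir / "counts.csv", parse_dates=["date"])
    dd = pd.read_csv(outdir / "degree_days.csv", parse_dates=["date"])
    feats = pd.read_csv(outdir / "features_pruned.csv")
    obs = counts[counts["life_stage"] == life_stage].merge(
        dd[["site_id", "date", "cdd"]], on=["site_id", "date"]
    )
    obs["year"] = obs["date"].dt.year
    return obs.merge(feats, on=["site_id", "year"], how="inner")


def stage_classify(cfg: RunConfig, outdir: Path) -> dict:
    summary = {}
    for stage in cfg.classify_stages:
        obs = _observation_table(cfg, outdir, stage)
        feature_cols = [
            c for c in obs.columns
            if c not in ("site_id", "date", "life_stage", "count", "year", "cdd")
        ]
        if stage == "egg":
            cuts = clf.ClassThresholds(cfg.egg_lower_pct, cfg.egg_upper_pct)
        else:
            cuts = clf.ClassThresholds(cfg.lower_pct, cfg.upper_pct)
        labels, cuts = clf.make_classes(obs["count"].to_numpy(), cuts)
        X = obs[list(TEMPORAL) + feature_cols].astype(float)
        seed = cfg.stage_seed(f"classify:{stage}")
        Xtr, Xte, ytr, yte = clf.split_train_test(
            X, np.asarray(labels), fraction=cfg.split_fraction, seed=seed
        )
        Xtr_n, norm = feat.zscore_normalize(Xtr)
        Xte_n = norm.transform(Xte)
        tuned = clf.tune_boosted_trees(
            Xtr_n, ytr, n_candidates=cfg.n_candidates, folds=cfg.folds, seed=seed
        )
        codes = pd.Categorical(yte, categories=list(tuned.classes_)).codes
        metrics = clf.multiclass_metrics(tuned.predict_proba(Xte_n), codes)
        imp = clf.permutation_importance(
            tuned.model, Xte_n, codes, n_perm=cfg.n_perm, seed=seed
        )
        _write_csv(imp.table, outdir / f"importance_{stage}.csv")
        payload = {
            "life_stage": stage,
            "class_cuts": {"lower": cuts.lower_cut, "upper": cuts.upper_cut},
            "winning_hyperparameters": tuned.params,
            "cv_auc": tuned.cv_auc,
            "test_metrics": metrics.to_dict(),
            "top_variables": imp.top(8),
        }
        (outdir / f"classifier_{stage}.json").write_text(json.dumps(payload, indent=2))
        summary[stage] = {
            "accuracy": metrics.accuracy, "macro_auc": metrics.macro_auc,
            "brier": metrics.brier, "top_variable": imp.table.iloc[0]["variable"],
        }
    return summary


def stage_gamm(
    cfg: RunConfig,
    outdir: Path,
    covariates: list[str] | None = None,
    focal: str | None = None,
) -> dict:
    summary = {}
    for stage in cfg.classify_stages:
        obs = _observation_table(cfg, outdir, stage)
        # P:A ratios are undefined where a class is absent from the buffer;
        # such incomplete columns stay in the tree model (which handles
        # missing values natively) but cannot enter the GAMM design
        complete = {c for c in obs.columns if not obs[c].isna().any()}
        if covariates is None:
            imp = pd.read_csv(outdir / f"importance_{stage}.csv")
            covs = [
                v for v in imp.sort_values("rank")["variable"]
                if v not in TEMPORAL and v in complete
            ][: cfg.top_k]
        else:
            covs = list(covariates)[: cfg.top_k]
        if focal is not None:
            if focal not in covs:
                covs = [focal] + covs[: cfg.top_k - 1]
            else:
                covs = [focal] + [c for c in covs if c != focal]
        norm_obs, norm = feat.zscore_normalize(obs, columns=covs)
        spec = GammSpec(
            life_stage=stage, covariates=tuple(covs),
            k_cdd=cfg.k_cdd, k_interaction=cfg.k_interaction,
        )
        design = build_design(norm_obs, spec)
        fit = fit_gamm(design)
        lo, hi = design.cdd_range
        grid = np.linspace(lo, hi, cfg.scenario_grid_points)
        pe = partial_effect_cdd(fit, grid)
        _write_csv(
            pd.DataFrame({"cdd": grid, "effect": pe.effect, "lo": pe.lo, "hi": pe.hi}),
            outdir / f"partial_effect_{stage}.csv",
        )
        focal = covs[0]
        pcts = feat.percentiles(obs[focal].to_numpy(), probs=cfg.percentiles)
        vals = {p: float(norm.to_normalized(focal, [raw])[0]) for p, raw in pcts.items()}
        scenarios = predict_scenario(fit, focal, vals, grid)
        frames = []
        for sc in scenarios:
            frames.append(pd.DataFrame({
                "focal": focal, "percentile": sc.percentile, "cdd": sc.grid,
                "mean": sc.mean, "lo": sc.lo, "hi": sc.hi,
            }))
        _write_csv(pd.concat(frames, ignore_index=True), outdir / f"scenarios_{stage}.csv")
        payload = {
            "life_stage": stage,
            "covariates": covs,
            "parametric": fit.parametric_table.to_dict(orient="records"),
            "smooths": fit.smooth_table.to_dict(orient="records"),
            "site_sd": fit.site_sd,
            "deviance_explained": fit.deviance_explained,
            "pseudo_r2": fit.pseudo_r2,
            "smoothing_criterion": fit.criterion,
            "focal_percentiles_raw": pcts,
        }
        (outdir / f"gamm_{stage}.json").write_text(json.dumps(payload, indent=2))
        summary[stage] = {
            "deviance_explained": fit.deviance_explained,
            "pseudo_r2": fit.pseudo_r2,
            "year_trend": float(
                fit.parametric_table.set_index("term").loc["year", "estimate"]
            ),
            "focal": focal,
        }
    return summary


STAGES = {
    "simulate": stage_simulate,
    "degree_days": stage_degree_days,
    "phenology": stage_phenology,
    "landscape": stage_landscape,
    "features": stage_features,
    "classify": stage_classify,
    "gamm": stage_gamm,
}

_DEPENDENCIES = {
    "degree_days": ("simulate",),
    "phenology": ("degree_days",),
    "landscape": ("simulate",),
    "features": ("phenology", "landscape"),
    "classify": ("features",),
    "gamm": ("features",),
}


def run_all(cfg: RunConfig) -> dict:
    """Run every enabled stage in dependency order; returns the run report."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_seed": cfg.seed, "stages": {}}
    failed: set[str] = set()
    for name in STAGES:
        entry: dict = {"status": "skipped"}
        if name in cfg.enabled:
            deps_bad = [d for d in _DEPENDENCIES.get(name, ()) if d in failed]
            if deps_bad:
                entry = {"status": "blocked", "failed_dependencies": deps_bad}
                failed.add(name)
            else:
                t0 = time.perf_counter()
                try:
                    result = STAGES[name](cfg, outdir)
                    entry = {
                        "status": "ok",
                        "elapsed_s": round(time.perf_counter() - t0, 3),
                        "result": result,
                    }
                except Exception as exc:  # recorded, dependents blocked
                    log.exception("stage %s failed", name)
                    entry = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
                    failed.add(name)
        report["stages"][name] = entry
    report["digests"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.suffix in (".csv", ".json", ".asc") and p.name != "report.json"
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
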