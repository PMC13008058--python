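"""Period-wise weather aggregation, lagging, correlation pruning, normalization.

Each site-year is summarised per seasonal period (winter/spring, one block
per generation, fall/winter) by the medians of tmin, tmax, soil temperature
and VPD, total precipitation, and means of solar radiation and snow-water
equivalent; days are assigned to a period by their cumulative degree days.
Because beetles that emerge in spring entered the soil the previous autumn,
the fall/winter block attached to a year is the *previous* calendar year's
(``prev_fall_winter``); the first year of a series is consumed as the lag
donor.  Correlated predictors (|Pearson r| > 0.7) are pruned greedily, and
retained columns are z-scored with statistics from a chosen fit partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology import GenerationPeriods

__all__ = [
    "assign_period",
    "aggregate_period_weather",
    "lag_fall_winter",
    "prune_correlated",
    "zscore_normalize",
    "percentiles",
    "CorrelationPruneReport",
    "Normalizer",
]

_MEDIAN_VARS = ("tmin", "tmax", "soil_t", "vpdmin", "vpdmax")
_SUM_VARS = ("precip",)
_MEAN_VARS = ("srad", "swe")


def assign_period(cdd, periods: GenerationPeriods):
    """Label observations by their CDD via half-open interval lookup."""
    return periods.label_for(cdd)


def aggregate_period_weather(
    weather: pd.DataFrame, dd: pd.DataFrame, periods: GenerationPeriods
) -> pd.DataFrame:
    """One row per site-year with per-period weather aggregates.

    Columns are ``<period>_<var>_<stat>`` (e.g. ``gen1_tmax_median``,
    ``fall_winter_precip_sum``).  A site-year-period with no days yields
    missing aggregates and a warning.
    """
    w = weather.merge(dd[["site_id", "date", "cdd"]], on=["site_id", "date"], how="inner")
    w["date"] = pd.to_datetime(w["date"])
    w["year"] = w["date"].dt.year
    w["period"] = assign_period(w["cdd"].to_numpy(), periods)

    aggs = {}
    for v in _MEDIAN_VARS:
        aggs[f"{v}_median"] = (v, "median")
    for v in _SUM_VARS:
        aggs[f"{v}_sum"] = (v, "sum")
    for v in _MEAN_VARS:
        aggs[f"{v}_mean"] = (v, "mean")
    grouped = w.groupby(["site_id", "year", "period"]).agg(**aggs)

    wide = grouped.unstack("period")
    wide.columns = [f"{period}_{stat}" for stat, period in wide.columns]
    wide = wide.reset_index()

    expected = [
        f"{lab}_{name}" for lab in periods.labels for name in aggs
    ]
    missing = [c for c in expected if c not in wide.columns or wide[c].isna().any()]
    if missing:
        warnings.warn(
            f"{len(missing)} period aggregates missing (empty periods)", stacklevel=2
        )
    for c in expected:
        if c not in wide.columns:
            wide[c] = np.nan
    return wide[["site_id", "year", *expected]]


def lag_fall_winter(features: pd.DataFrame) -> pd.DataFrame:
    """Replace fall/winter columns with the previous year's values.

    For every site-year y the ``fall_winter_*`` aggregates of year y-1 are
    attached as ``prev_fall_winter_*``; rows without a preceding year
    (first year, gap years) are dropped.  The contemporaneous fall/winter
    columns are removed — they describe conditions *after* the season being
    modelled.
    """
    fw_cols = [c for c in features.columns if c.startswith("fall_winter_")]
    donor = features[["site_id", "year", *fw_cols]].copy()
    donor["year"] = donor["year"] + 1
    donor = donor.rename(columns={c: "prev_" + c for c in fw_cols})
    out = features.drop(columns=fw_cols).merge(donor, on=["site_id", "year"], how="inner")
    if out.empty:
        warnings.warn("no site-year has a preceding year; output is empty", stacklevel=2)
    return out


@dataclass
class CorrelationPruneReport:
    dropped: list[str] = field(default_factory=list)
    trigger_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped": self.dropped,
            "trigger_pairs": [
                {"kept_candidate": a, "dropped": b, "abs_r": r}
                for a, b, r in self.trigger_pairs
            ],
            "retained": self.retained,
        }


def prune_correlated(
    features: pd.DataFrame, threshold: float = 0.7, columns: list[str] | None = None
) -> tuple[pd.DataFrame, CorrelationPruneReport]:
    """Greedy correlation pruning until all pairwise |r| <= threshold.

    Repeatedly find the worst offending pair and drop whichever member has
    the larger mean absolute correlation against all remaining variables
    (ties broken by column order, so the result is deterministic).
    Zero-variance columns are dropped first.
    """
    if columns is None:
        columns = [
            c for c in features.columns
            if c not in ("site_id", "year") and pd.api.types.is_numeric_dtype(features[c])
        ]
    report = CorrelationPruneReport()
    cols = list(columns)
    for c in list(cols):
        if features[c].std(ddof=1) == 0 or features[c].isna().all():
            report.dropped.append(c)
            report.trigger_pairs.append((c, c, float("nan")))
            cols.remove(c)
    while len(cols) >= 2:
        r = features[cols].corr().abs()
        np.fill_diagonal(r.values, 0.0)
        worst = float(r.values.max())
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(r.values), r.shape)
        a, b = r.index[i], r.columns[j]
        mean_abs = r.mean()
        drop = b if mean_abs[b] >= mean_abs[a] else a
        keep = a if drop == b else b
        report.dropped.append(drop)
        report.trigger_pairs.append((keep, drop, worst))
        cols.remove(drop)
    report.retained = cols
    if len(cols) >= 2:
        check = features[cols].corr().abs()
        np.fill_diagonal(check.values, 0.0)
        assert check.values.max() <= threshold + 1e-12
    return features[["site_id", "year", *cols]] if "site_id" in features else features[cols], report


@dataclass
class Normalizer:
    """Column means/sds (n-1 denominator) fitted on one partition."""

    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means.index:
            out[c] = (df[c] - self.means[c]) / self.sds[c]
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means.index:
            out[c] = df[c] * self.sds[c] + self.means[c]
        return out

    def to_normalized(self, column: str, raw_values):
        return (np.asarray(raw_values, dtype=float) - self.means[column]) / self.sds[column]


def zscore_normalize(
    features: pd.DataFrame,
    fit_rows: np.ndarray | pd.Index | None = None,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, Normalizer]:
    """Z-score columns using statistics from ``fit_rows`` (default: all rows)."""
    if columns is None:
        columns = [
            c for c in features.columns
            if c not in ("site_id", "year") and pd.api.types.is_numeric_dtype(features[c])
        ]
    fit = features if fit_rows is None else features.loc[fit_rows]
    means = fit[columns].mean()
    sds = fit[columns].std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero standard deviation on fit rows for: {zero}")
    norm = Normalizer(means=means, sds=sds)
    return norm.transform(features), norm


def percentiles(values, probs=(10, 50, 90)) -> dict[int, float]:
    """Empirical raw-scale quantiles (linear interpolation), needs >= 10 values."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 10:
        raise ValueError(f"need at least 10 values, got {len(values)}")
    qs = np.percentile(values, probs)  # linear interpolation convention
    return {int(p): float(q) for p, q in zip(probs, qs)}
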