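"""Phenology landmark detection: closed-form curves and simulation recovery."""

import numpy as np
import pandas as pd
import pytest

from beetlephen.degree_days import cumulative_dd
from beetlephen.phenology import (
    DegenerateFitError,
    GenerationPeriods,
    InsufficientEventsError,
    NoEventsError,
    build_periods,
    detect_events,
    fit_cdd_profile,
)
from beetlephen.simulate import SimConfig, TruthRecord, Hump, gen_counts, gen_sites, gen_weather


def true_landmarks(truth, lo, hi, stage="adult"):
    """Oracle: landmarks of the exact phenology curve centred over [lo, hi].

    Peaks/valleys are extrema of the dense summed curve (overlapping humps
    shift them away from the individual hump centres); crossings of the
    centred curve give colonization and season end.
    """
    from scipy.signal import argrelmax, argrelmin

    x = np.linspace(lo, hi, 8000)
    g = truth.phenology(x, stage)
    c = g - np.trapezoid(g, x) / (hi - lo)
    pk = [i for i in argrelmax(c)[0] if c[i] > 0]
    peaks = [float(x[i]) for i in pk]
    valleys = []
    for a, b in zip(pk[:-1], pk[1:]):
        valleys.append(float(x[a + np.argmin(c[a : b + 1])]))
    col = float(x[np.flatnonzero((c[:-1] < 0) & (c[1:] >= 0))[0]])
    down = np.flatnonzero((c[:-1] > 0) & (c[1:] <= 0))
    end = float(x[down[-1]]) if len(down) else hi
    return {"colonization": col, "peaks": peaks, "breakpoints": valleys, "end": end}


# ---- detect_events on closed-form curves ----------------------------------

def test_single_hump_closed_form_curve():
    grid = np.arange(0.0, 2200.0, 5.0)
    # sin-like hump: zero at 250 and 1900, max at 1075 (midpoint)
    v = np.where(
        (grid >= 250) & (grid <= 1900),
        np.sin(np.pi * (grid - 250) / 1650),
        -0.2,
    )
    ev = detect_events((grid, v))
    assert ev.colonization_cdd == pytest.approx(250, abs=6)
    assert len(ev.peak_cdds) == 1 and ev.peak_cdds[0] == pytest.approx(1075, abs=6)
    assert ev.breakpoint_cdds == []
    assert ev.season_end_cdd == pytest.approx(1900, abs=6)


def test_two_hump_curve_breakpoint_at_valley():
    grid = np.arange(0.0, 2200.0, 2.0)
    v = (
        2.0 * np.exp(-0.5 * ((grid - 500) / 150) ** 2)
        + 1.6 * np.exp(-0.5 * ((grid - 1400) / 170) ** 2)
        - 0.4
    )
    ev = detect_events((grid, v))
    assert len(ev.peak_cdds) == 2
    assert ev.peak_cdds[0] == pytest.approx(500, abs=10)
    assert ev.peak_cdds[1] == pytest.approx(1400, abs=10)
    # valley location from the same expression, dense argmin
    seg = (grid > 500) & (grid < 1400)
    assert ev.breakpoint_cdds[0] == pytest.approx(grid[seg][np.argmin(v[seg])], abs=10)


def test_monotone_negative_curve_raises():
    grid = np.arange(0.0, 1000.0, 5.0)
    with pytest.raises(NoEventsError):
        detect_events((grid, -1.0 - grid / 1000))


def test_small_wiggles_suppressed_by_prominence():
    rng = np.random.default_rng(0)
    grid = np.arange(0.0, 2000.0, 5.0)
    v = 2.0 * np.exp(-0.5 * ((grid - 800) / 200) ** 2) - 0.3
    v += 0.02 * rng.standard_normal(len(grid))
    ev = detect_events((grid, v), prominence_frac=0.05)
    assert len(ev.peak_cdds) == 1


# ---- build_periods --------------------------------------------------------

def test_periods_reproduce_study_boundaries():
    from beetlephen.phenology import PhenologyEvents

    ev = PhenologyEvents(
        colonization_cdd=203.0, peak_cdds=[500.0, 1400.0, 1971.0],
        breakpoint_cdds=[936.0, 1800.0], season_end_cdd=2300.0,
    )
    per = build_periods(ev, n_generations=2)
    assert per.boundaries == [203.0, 936.0, 1800.0]
    assert per.labels == ["winter_spring", "gen1", "gen2", "fall_winter"]
    assert list(per.label_for([100, 203, 935, 936, 1800, 5000])) == [
        "winter_spring", "gen1", "gen1", "gen2", "fall_winter", "fall_winter",
    ]


def test_periods_partition_every_cdd_once():
    per = GenerationPeriods(boundaries=[203.0, 936.0, 1800.0])
    cdd = np.linspace(0, 4000, 1001)
    labels = per.label_for(cdd)
    ivals = per.intervals()
    for c, lab in zip(cdd, labels):
        hits = [name for name, a, b in ivals if a <= c < b]
        assert hits == [lab]


def test_periods_two_hump_season_end_fallback():
    from beetlephen.phenology import PhenologyEvents

    ev = PhenologyEvents(250.0, [500.0, 1400.0], [950.0], 1900.0)
    per = build_periods(ev, n_generations=2)
    assert per.boundaries == [250.0, 950.0, 1900.0]


def test_periods_insufficient_peaks():
    from beetlephen.phenology import PhenologyEvents

    ev = PhenologyEvents(250.0, [500.0], [], 1900.0)
    with pytest.raises(InsufficientEventsError):
        build_periods(ev, n_generations=2)


def test_negative_cdd_rejected():
    per = GenerationPeriods(boundaries=[203.0, 936.0, 1800.0])
    with pytest.raises(ValueError):
        per.label_for([-1.0])


# ---- fit_cdd_profile ------------------------------------------------------

def _sim(truth, seed, n_sites=60, years=(2019, 2020)):
    cfg = SimConfig(n_sites=n_sites, years=years, extent_m=5000.0, seed=seed,
                    truth=truth)
    sites = gen_sites(cfg)
    weather = gen_weather(sites, cfg)
    dd = cumulative_dd(weather)
    counts = gen_counts(sites, weather, None, truth, cfg, dd=dd)
    return counts, dd


def test_constant_counts_give_flat_profile():
    truth = TruthRecord(alpha=1.5, humps=(), covariate_effects=(),
                        year_trend=0.0, sigma_site=0.0)
    counts, dd = _sim(truth, seed=3, n_sites=40)
    curve = fit_cdd_profile(counts, dd, "adult")
    assert np.abs(curve.bin_coefficients).max() < 0.25
    assert np.abs(curve.smooth).max() < 0.15


def test_single_hump_peak_recovered_within_one_bin():
    truth = TruthRecord(alpha=0.3, humps=(Hump(500.0, 150.0, 2.5),),
                        covariate_effects=(), year_trend=0.0, sigma_site=0.0)
    counts, dd = _sim(truth, seed=4, n_sites=80)
    curve = fit_cdd_profile(counts, dd, "adult", bin_width=25.0)
    assert curve.grid[np.argmax(curve.smooth)] == pytest.approx(500.0, abs=25.0)


def test_all_zero_counts_degenerate():
    truth = TruthRecord(alpha=-30.0, humps=(), covariate_effects=(),
                        year_trend=0.0, sigma_site=0.0)
    counts, dd = _sim(truth, seed=5, n_sites=10, years=(2020,))
    with pytest.raises(DegenerateFitError):
        fit_cdd_profile(counts, dd, "adult")


def test_two_hump_landmark_recovery_single_run():
    """Fitted landmarks match the exact-curve oracle within one bin (25 CDD)."""
    truth = TruthRecord()  # default two-hump adult phenology
    counts, dd = _sim(truth, seed=6, n_sites=100, years=(2019, 2020, 2021))
    obs = counts.query("life_stage == 'adult'").merge(dd, on=["site_id", "date"])
    lo, hi = obs["cdd"].min(), obs["cdd"].max()
    want = true_landmarks(truth, lo, hi)

    curve = fit_cdd_profile(counts, dd, "adult", bin_width=25.0)
    ev = detect_events(curve)
    assert len(ev.peak_cdds) >= 2
    got_peaks = sorted(ev.peak_cdds, key=lambda p: min(abs(p - w) for w in want["peaks"]))[:2]
    for w in want["peaks"]:
        assert min(abs(p - w) for p in got_peaks) <= 25.0
    assert abs(ev.colonization_cdd - want["colonization"]) <= 25.0
    assert abs(ev.breakpoint_cdds[0] - want["breakpoints"][0]) <= 25.0


def test_bin_width_robustness():
    truth = TruthRecord()
    counts, dd = _sim(truth, seed=7, n_sites=80, years=(2019, 2020))
    e25 = detect_events(fit_cdd_profile(counts, dd, "adult", bin_width=25.0))
    e50 = detect_events(fit_cdd_profile(counts, dd, "adult", bin_width=50.0))
    assert abs(e25.peak_cdds[0] - e50.peak_cdds[0]) <= 50.0
    assert abs(e25.colonization_cdd - e50.colonization_cdd) <= 50.0
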