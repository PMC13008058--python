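"""Single-sine degree days with a horizontal cutoff.

The daily temperature trace is modelled as one sine period passing through
(tmin, tmax).  Degree days are the area between the lower developmental
threshold ``L`` and the trace, with temperatures above the upper threshold
``U`` counted as if they were at ``U`` (horizontal cutoff).  Accumulation
starts at a fixed biofix (January 1 by default) and resets every calendar
year.  Thresholds default to the Colorado potato beetle values of 11/31 °C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DegreeDayParams", "single_sine_dd", "cumulative_dd", "MissingDatesError"]


class MissingDatesError(ValueError):
    """Raised when a site-year weather series has gaps."""

    def __init__(self, gaps: dict):
        self.gaps = gaps
        msg = "; ".join(
            f"site {s}: missing {', '.join(str(d.date()) for d in days[:5])}"
            + ("..." if len(days) > 5 else "")
            for s, days in gaps.items()
        )
        super().__init__(f"weather series has gaps: {msg}")


@dataclass(frozen=True)
class DegreeDayParams:
    """Thresholds and biofix for degree-day accumulation.

    lower/upper are in °C; ``biofix`` is a month-day string (``"01-01"``).
    Only the horizontal cutoff is implemented.
    """

    lower: float = 11.0
    upper: float = 31.0
    biofix: str = "01-01"
    cutoff: str = "horizontal"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"lower threshold must be < upper ({self.lower} >= {self.upper})")
        if self.cutoff != "horizontal":
            raise ValueError(f"unsupported cutoff {self.cutoff!r}")


def single_sine_dd(tmin, tmax, params: DegreeDayParams = DegreeDayParams()):
    """Daily degree days by the single sine method with horizontal cutoff.

    Vectorised over ``tmin``/``tmax`` (broadcast together).  The six analytic
    cases depend on where the day's sine trace sits relative to the two
    thresholds; degenerate flat days (tmin == tmax) reduce to the clipped
    mean without hitting the arcsin branches.

    Returns degree days in °C·day, in ``[0, upper - lower]``.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin > tmax encountered")
    L, U = params.lower, params.upper

    m = (tmax + tmin) / 2.0  # mean
    w = (tmax - tmin) / 2.0  # half amplitude
    out = np.empty(np.broadcast(tmin, tmax).shape, dtype=float)
    m, w, tmn, tmx = np.broadcast_arrays(m, w, tmin, tmax)

    below = tmx <= L
    above = tmn >= U
    inside = (~below) & (~above) & (tmn >= L) & (tmx <= U)
    out[below] = 0.0
    out[above] = U - L
    out[inside] = m[inside] - L

    # intercepted cases need the sine geometry; guard w=0 (already covered)
    rest = ~(below | above | inside)
    if np.any(rest):
        mr, wr = m[rest], w[rest]
        tmnr, tmxr = tmn[rest], tmx[rest]
        vals = np.empty(mr.shape)

        cross_lo = tmnr < L  # trace dips below L
        cross_hi = tmxr > U  # trace exceeds U
        with np.errstate(invalid="ignore"):
            th1 = np.arcsin(np.clip((L - mr) / np.where(wr > 0, wr, 1.0), -1, 1))
            th2 = np.arcsin(np.clip((U - mr) / np.where(wr > 0, wr, 1.0), -1, 1))

        # case iv: tmin < L <= tmax <= U
        iv = cross_lo & ~cross_hi
        vals[iv] = ((mr - L) * (np.pi / 2 - th1) + wr * np.cos(th1))[iv] / np.pi
        # case v: L <= tmin, tmax > U
        v = ~cross_lo & cross_hi
        vals[v] = (
            (mr - L) * (th2 + np.pi / 2) + (U - L) * (np.pi / 2 - th2) - wr * np.cos(th2)
        )[v] / np.pi
        # case vi: tmin < L, tmax > U
        vi = cross_lo & cross_hi
        vals[vi] = (
            (mr - L) * (th2 - th1) + wr * (np.cos(th1) - np.cos(th2)) + (U - L) * (np.pi / 2 - th2)
        )[vi] / np.pi

        out[rest] = vals
    # clamp tiny negative round-off
    np.clip(out, 0.0, U - L, out=out)
    return out if out.ndim else float(out)


def cumulative_dd(weather: pd.DataFrame, params: DegreeDayParams = DegreeDayParams()) -> pd.DataFrame:
    """Cumulative degree days per site from the biofix, resetting each year.

    ``weather`` needs columns site_id, date, tmin, tmax, one row per
    site-date with no gaps inside each site-year (a gap raises
    :class:`MissingDatesError` listing the missing days).

    Returns a DataFrame with site_id, date, daily_dd, cdd.
    """
    w = weather[["site_id", "date", "tmin", "tmax"]].copy()
    w["date"] = pd.to_datetime(w["date"])
    w = w.sort_values(["site_id", "date"]).reset_index(drop=True)

    gaps = {}
    for site, grp in w.groupby("site_id", sort=False):
        for year, g in grp.groupby(grp["date"].dt.year):
            full = pd.date_range(g["date"].min(), g["date"].max(), freq="D")
            missing = full.difference(g["date"])
            if len(missing):
                gaps.setdefault(site, []).extend(list(missing))
    if gaps:
        raise MissingDatesError(gaps)

    w["daily_dd"] = single_sine_dd(w["tmin"].to_numpy(), w["tmax"].to_numpy(), params)
    # accumulation restarts at the biofix of each calendar year
    bm, bd = (int(x) for x in params.biofix.split("-"))
    doy_key = w["date"].dt.year.astype(str)
    if (bm, bd) != (1, 1):  # season year flips at the biofix
        after = (w["date"].dt.month > bm) | ((w["date"].dt.month == bm) & (w["date"].dt.day >= bd))
        doy_key = (w["date"].dt.year - (~after).astype(int)).astype(str)
    w["cdd"] = w.groupby(["site_id", doy_key], sort=False)["daily_dd"].cumsum()
    return w[["site_id", "date", "daily_dd", "cdd"]]
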