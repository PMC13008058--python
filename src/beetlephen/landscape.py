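"""Land-cover reclassification and per-site buffer metrics.

Works on a flat planar grid (no CRS): a categorical raster with square
cells, sites given as (x, y) in metres.  Metrics follow the common
landscape-ecology conventions — cell-centre-in-circle buffer membership,
4-connectivity patch edges — within a circular buffer (1 km default, the
scale at which crop composition around a potato field is summarised).

Eleven cover classes are used: the four focal rotation crops kept separate
(potato, corn, soybean, wheat), grouped crop classes (legume, other
cereals, forage, other crop), and three non-crop classes (water, developed,
semi-natural).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "LandscapeRaster",
    "reclassify",
    "buffer_cells",
    "class_area_ha",
    "perimeter_area_ratio",
    "enn_to_class",
    "shannon_diversity",
    "buffer_metrics_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "BufferEdgeError",
    "ReclassError",
]

CLASSES = (
    "Potato",
    "Corn",
    "Soybean",
    "Wheat",
    "Legume",
    "OtherCereals",
    "Forage",
    "OtherCrop",
    "Water",
    "Developed",
    "SemiNatural",
)


class BufferEdgeError(ValueError):
    """Buffer extends beyond the raster; clipped buffers are not computed."""


class ReclassError(KeyError):
    """A raw land-cover code has no entry in the reclassification table."""


@dataclass
class LandscapeRaster:
    """Categorical grid with square cells on a planar coordinate system.

    ``grid[row, col]`` holds an integer class code; row 0 is the top
    (largest y).  ``origin`` is the (x, y) of the lower-left corner.
    """

    grid: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    class_names: tuple[str, ...] = CLASSES

    @property
    def shape(self):
        return self.grid.shape

    def cell_centers(self):
        """(x, y) coordinate arrays of every cell centre (2-D, grid shape)."""
        nrow, ncol = self.grid.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_size_m
        ys = y0 + (nrow - np.arange(nrow) - 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def code_of(self, class_name: str) -> int:
        return self.class_names.index(class_name)


def reclassify(raster: LandscapeRaster, table: dict[int, str]) -> LandscapeRaster:
    """Map raw cover codes onto the eleven analysis classes.

    ``table`` maps each raw integer code to a class name in :data:`CLASSES`.
    Any code present in the grid but absent from the table raises
    :class:`ReclassError` naming the code.
    """
    present = np.unique(raster.grid)
    missing = [int(c) for c in present if int(c) not in table]
    if missing:
        raise ReclassError(f"unmapped raw codes: {missing}")
    bad = sorted({v for v in table.values() if v not in CLASSES})
    if bad:
        raise ReclassError(f"unknown target classes: {bad}")
    lut = np.zeros(int(present.max()) + 1, dtype=np.int16)
    for raw, name in table.items():
        if raw <= present.max():
            lut[raw] = CLASSES.index(name)
    return LandscapeRaster(
        grid=lut[raster.grid], cell_size_m=raster.cell_size_m,
        origin=raster.origin, class_names=CLASSES,
    )


def buffer_cells(raster: LandscapeRaster, site_xy, radius_m: float = 1000.0) -> np.ndarray:
    """Boolean mask of cells whose centres lie within ``radius_m`` of the site.

    Raises :class:`BufferEdgeError` when the circle is clipped by the raster
    extent: metrics on partial buffers would not be comparable across sites.
    """
    x, y = site_xy
    nrow, ncol = raster.grid.shape
    x0, y0 = raster.origin
    if (
        x - radius_m < x0
        or x + radius_m > x0 + ncol * raster.cell_size_m
        or y - radius_m < y0
        or y + radius_m > y0 + nrow * raster.cell_size_m
    ):
        raise BufferEdgeError(
            f"buffer of {radius_m} m around ({x:.0f}, {y:.0f}) exceeds raster extent"
        )
    cx, cy = raster.cell_centers()
    return (cx - x) ** 2 + (cy - y) ** 2 <= radius_m**2


def class_area_ha(cells: np.ndarray, raster: LandscapeRaster, class_name: str) -> float:
    """Area (ha) covered by one class within the buffer mask."""
    code = raster.code_of(class_name)
    n = int(np.count_nonzero(cells & (raster.grid == code)))
    return n * raster.cell_size_m**2 / 10_000.0


def perimeter_area_ratio(cells: np.ndarray, raster: LandscapeRaster, class_name: str):
    """Class boundary length / class area (m per m²) within the buffer.

    Edges are counted with 4-connectivity: a cell side bordering a
    different class, the raster edge, or the buffer boundary contributes
    one cell-side length.  All patches of the class are pooled (class-total
    edge over class-total area).  Returns ``nan`` when the class is absent.
    """
    code = raster.code_of(class_name)
    member = cells & (raster.grid == code)
    n = int(member.sum())
    if n == 0:
        return float("nan")
    padded = np.pad(member, 1, constant_values=False)
    edges = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        edges += int((member & ~neigh).sum())
    s = raster.cell_size_m
    return edges * s / (n * s**2)


def enn_to_class(raster: LandscapeRaster, site_xy, class_name: str):
    """Euclidean distance (m) from the site to the nearest cell centre of a class.

    Searched over the whole raster, not just the buffer.  Returns ``nan``
    when the class is absent anywhere.
    """
    code = raster.code_of(class_name)
    mask = raster.grid == code
    if not mask.any():
        return float("nan")
    cx, cy = raster.cell_centers()
    d2 = (cx[mask] - site_xy[0]) ** 2 + (cy[mask] - site_xy[1]) ** 2
    return float(math.sqrt(d2.min()))


def shannon_diversity(cells: np.ndarray, raster: LandscapeRaster) -> float:
    """Shannon diversity H (nats) over class proportions inside the buffer."""
    if not cells.any():
        raise ValueError("empty buffer cell set")
    codes = raster.grid[cells]
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def buffer_metrics_table(
    raster: LandscapeRaster, sites: pd.DataFrame, radius_m: float = 1000.0
) -> pd.DataFrame:
    """Per-site metric table: per-class area and P:A ratio, ENN to potato, H.

    ``sites`` needs columns site_id, x, y.  Column names are lower-case
    (``potato_area_ha``, ``corn_pa_ratio``, ``enn_potato_m``, ``shannon_h``).
    """
    rows = []
    for r in sites.itertuples(index=False):
        cells = buffer_cells(raster, (r.x, r.y), radius_m)
        rec = {"site_id": r.site_id}
        for name in raster.class_names:
            key = name.lower()
            rec[f"{key}_area_ha"] = class_area_ha(cells, raster, name)
            rec[f"{key}_pa_ratio"] = perimeter_area_ratio(cells, raster, name)
        rec["enn_potato_m"] = enn_to_class(raster, (r.x, r.y), "Potato")
        rec["shannon_h"] = shannon_diversity(cells, raster)
        rows.append(rec)
    return pd.DataFrame(rows)


# -- ESRI ASCII grid I/O ----------------------------------------------------
# Plain-text raster exchange format: six header lines then whitespace-
# separated integer rows, top row first.

def write_ascii_grid(path, raster: LandscapeRaster) -> None:
    nrow, ncol = raster.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {raster.origin[0]}\n")
        fh.write(f"yllcorner {raster.origin[1]}\n")
        fh.write(f"cellsize {raster.cell_size_m}\n")
        fh.write("NODATA_value -9999\n")
        for row in raster.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path, class_names: tuple[str, ...] = CLASSES) -> LandscapeRaster:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        k, v = line.split()
        header[k.lower()] = float(v)
    grid = np.loadtxt(lines[6:], dtype=np.int16)
    grid = np.atleast_2d(grid)
    return LandscapeRaster(
        grid=grid,
        cell_size_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        class_names=class_names,
    )
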