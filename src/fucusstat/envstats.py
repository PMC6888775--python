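"""Environmental raster statistics.

Gridded environmental variables (salinity, exposure, Secchi depth, total
nitrogen and phosphorus) are held as :class:`EnvironmentGrid` objects backed
by the ESRI ASCII grid format. Values are extracted at point locations with
nearest-cell (point-in-cell) semantics, zonal means are computed over polygon
zones by a cell-centre membership test, and the covariate table is screened
for collinearity with pairwise Pearson correlations.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import shape as shapely_shape

from fucusstat.errors import InputError

log = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0


@dataclass
class EnvironmentGrid:
    """One gridded environmental variable at its own resolution.

    ``values`` follows the ESRI ASCII row convention: row 0 is the
    northernmost row. ``x_origin``/``y_origin`` are the coordinates of the
    lower-left corner of the grid.
    """

    name: str
    x_origin: float
    y_origin: float
    cell_size: float
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError(f"grid '{self.name}': values must be 2-D")
        if self.cell_size <= 0:
            raise InputError(f"grid '{self.name}': cell_size must be > 0")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise InputError(f"grid '{self.name}': non-finite values present")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x_origin,
            self.y_origin,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of all cell centres, shaped like ``values``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.x_origin + (cols + 0.5) * self.cell_size
        ys = self.y_origin + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[out == self.nodata] = np.nan
        return out


def read_ascii_grid(path: str | Path, name: str | None = None) -> EnvironmentGrid:
    """Read an ESRI ASCII grid (``.asc``)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value", "xllcenter", "yllcenter"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise InputError(f"{path}: missing ASCII grid header '{req}'")
    values = np.array(list(itertools.chain.from_iterable(rows)), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise InputError(
            f"{path}: expected {nrows * ncols} cells, found {values.size}"
        )
    cell = header["cellsize"]
    # xllcenter/yllcenter variants are shifted by half a cell
    x0 = header.get("xllcorner", header.get("xllcenter", 0.0) - cell / 2)
    y0 = header.get("yllcorner", header.get("yllcenter", 0.0) - cell / 2)
    return EnvironmentGrid(
        name=name or path.stem,
        x_origin=x0,
        y_origin=y0,
        cell_size=cell,
        values=values.reshape(nrows, ncols),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def write_ascii_grid(grid: EnvironmentGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (``.asc``)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def extract_at_points(
    grid: EnvironmentGrid, x: Sequence[float], y: Sequence[float]
) -> np.ndarray:
    """Grid value of the cell containing each point (no interpolation).

    Points outside the grid extent or on nodata cells yield NaN; callers are
    expected to drop those rows (a warning is logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = np.floor((x - grid.x_origin) / grid.cell_size).astype(int)
    # row 0 is the top (north) row
    row = np.floor(
        (grid.y_origin + grid.n_rows * grid.cell_size - y) / grid.cell_size
    ).astype(int)
    # points exactly on the top/right edge belong to the edge cell
    col = np.where((x == grid.bounds[2]), grid.n_cols - 1, col)
    row = np.where((y == grid.bounds[3]), 0, row)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    out = np.full(x.shape, np.nan)
    out[inside] = grid.values[row[inside], col[inside]]
    out[out == grid.nodata] = np.nan
    n_bad = int(np.sum(~np.isfinite(out)))
    if n_bad:
        log.warning(
            "extract_at_points(%s): %d of %d points outside extent or nodata",
            grid.name, n_bad, x.size,
        )
    return out


def zonal_mean(grid: EnvironmentGrid, zone) -> float:
    """Arithmetic mean of cell values whose centres fall inside ``zone``.

    ``zone`` is a shapely geometry, a GeoJSON-like mapping, or an
    (xmin, ymin, xmax, ymax) rectangle. Nodata cells are excluded. Returns
    NaN (with a warning) when no cell centre falls inside the zone.
    """
    if isinstance(zone, (tuple, list)) and len(zone) == 4:
        geom = shapely.box(*zone)
    elif isinstance(zone, Mapping):
        geom = shapely_shape(zone)
    else:
        geom = zone
    xs, ys = grid.cell_centers()
    xmin, ymin, xmax, ymax = geom.bounds
    pre = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
    inside = np.zeros_like(pre)
    if pre.any():
        inside[pre] = shapely.contains_xy(geom, xs[pre], ys[pre])
    vals = grid.values[inside]
    vals = vals[vals != grid.nodata]
    if vals.size == 0:
        warnings.warn(
            f"zonal_mean({grid.name}): no cell centres inside zone", stacklevel=2
        )
        return float("nan")
    return float(vals.mean())


def zonal_means_table(
    grids: Mapping[str, EnvironmentGrid], zones: Sequence
) -> pd.DataFrame:
    """One row per zone, one column per grid variable (zonal means)."""
    records = []
    for z in zones:
        if isinstance(z, Mapping):
            geom = z["geometry"]
            zone_id = z.get("zone_id")
        else:
            geom = getattr(z, "geometry", None)
            if geom is None:
                geom = getattr(z, "rect", z)
            zone_id = getattr(z, "zone_id", None)
        rec = {"zone_id": zone_id}
        for name, grid in grids.items():
            rec[name] = zonal_mean(grid, geom)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def load_zones_geojson(path: str | Path) -> list[dict]:
    """Read zone polygons from a GeoJSON FeatureCollection.

    Returns a list of dicts with ``zone_id`` and shapely ``geometry``.
    """
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {}) or {}
        out.append(
            {
                "zone_id": props.get("zone_id", props.get("id")),
                "geometry": shapely_shape(feat["geometry"]),
                "properties": props,
            }
        )
    return out


def correlation_matrix(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p values (t distribution, n-2 df).

    Rows with any missing value are dropped. Zero-variance columns yield NaN
    correlations and are flagged with a warning.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    data = table[cols].dropna()
    if len(data) < 3:
        raise InputError("correlation_matrix requires >= 3 complete rows")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    degenerate = [c for c in cols if np.std(data[c].to_numpy()) == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns, r undefined: {degenerate}")
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data[cols[i]].to_numpy(), data[cols[j]].to_numpy()
            if cols[i] in degenerate or cols[j] in degenerate:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


@dataclass
class CollinearityResult:
    dropped: list[str]
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def collinearity_screen(
    r_matrix: pd.DataFrame,
    threshold: float = 0.8,
    victims: Mapping[frozenset, str] | None = None,
) -> CollinearityResult:
    """Decide which variables to drop from pairs with |r| >= threshold.

    The victim of a flagged pair is configured, not inferred: ``victims``
    maps a frozenset pair to the variable to drop. By default ``ptot`` is
    dropped when paired with ``ntot``; for unconfigured pairs the variable
    appearing later in column order is dropped.
    """
    if victims is None:
        victims = {frozenset({"ntot", "ptot"}): "ptot"}
    cols = list(r_matrix.columns)
    dropped: list[str] = []
    flagged: list[tuple[str, str, float]] = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rab = r_matrix.loc[a, b]
            if np.isfinite(rab) and abs(rab) >= threshold:
                flagged.append((a, b, float(rab)))
                victim = victims.get(frozenset({a, b}), b)
                if victim not in dropped:
                    dropped.append(victim)
                    log.info(
                        "collinearity_screen: |r(%s,%s)|=%.3f >= %.2f, dropping %s",
                        a, b, abs(rab), threshold, victim,
                    )
    return CollinearityResult(dropped=dropped, flagged_pairs=flagged)
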