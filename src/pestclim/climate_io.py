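"""Gridded monthly climate I/O and monthly-to-weekly conversion.

The mechanistic engine runs on a weekly time step while climate layers come
as 12 monthly fields per variable. This module defines the grid geometry,
the in-memory climate container, plain-text raster I/O (ESRI ASCII grid,
one file per variable per month), occurrence CSV loading, and the
monthly->weekly interpolation the engine consumes.

Conventions: cell-centre registration, latitude row 0 is the northernmost
row, longitudes in [-180, 180), WGS84 decimal degrees. Ocean / missing cells
travel as a boolean land mask, never as sentinel values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
YEAR_DAYS = 365
N_WEEKS = 52
CLIMATE_VARS = ("tmin", "tmax", "rain", "rh09", "rh15")

# Week w covers days [7w, 7w+7); the one-day remainder of a 365-day year is
# folded into week 51 (8 days).
_WEEK_OF_DAY = np.minimum(np.arange(YEAR_DAYS) // 7, N_WEEKS - 1)
_DAYS_PER_WEEK = np.bincount(_WEEK_OF_DAY, minlength=N_WEEKS).astype(float)

_MONTH_STARTS = np.concatenate([[0.0], np.cumsum(MONTH_LENGTHS)])[:12]
_MONTH_MIDS = _MONTH_STARTS + MONTH_LENGTHS / 2.0
_MONTH_OF_DAY = np.searchsorted(np.cumsum(MONTH_LENGTHS), np.arange(YEAR_DAYS), side="right")


def _temperature_weight_matrix() -> np.ndarray:
    """(52, 12) matrix W with weekly = W @ monthly.

    Daily values are linear interpolations between month mid-points with
    periodic December->January wrap; a week's value is the mean of its days.
    """
    day_centers = np.arange(YEAR_DAYS) + 0.5
    xs = np.concatenate([[_MONTH_MIDS[-1] - YEAR_DAYS], _MONTH_MIDS, [_MONTH_MIDS[0] + YEAR_DAYS]])
    daily_w = np.empty((YEAR_DAYS, 12))
    for m in range(12):
        basis = np.zeros(12)
        basis[m] = 1.0
        ys = np.concatenate([[basis[-1]], basis, [basis[0]]])
        daily_w[:, m] = np.interp(day_centers, xs, ys)
    weekly = np.zeros((N_WEEKS, 12))
    for w in range(N_WEEKS):
        sel = _WEEK_OF_DAY == w
        weekly[w] = daily_w[sel].sum(axis=0) / sel.sum()
    return weekly


def _rain_weight_matrix() -> np.ndarray:
    """(52, 12) matrix apportioning each month's total by day overlap."""
    weekly = np.zeros((N_WEEKS, 12))
    for d in range(YEAR_DAYS):
        m = _MONTH_OF_DAY[d]
        weekly[_WEEK_OF_DAY[d], m] += 1.0 / MONTH_LENGTHS[m]
    return weekly


TEMP_WEEKLY_WEIGHTS = _temperature_weight_matrix()
RAIN_WEEKLY_WEIGHTS = _rain_weight_matrix()


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid, cell-centre registered, north-up.

    ``origin_lon``/``origin_lat`` are the coordinates of the grid's
    outer *edge* (west edge, north edge).
    """

    n_rows: int
    n_cols: int
    cell_size_deg: float
    origin_lon: float = -180.0
    origin_lat: float = 90.0
    land_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        south = self.origin_lat - self.n_rows * self.cell_size_deg
        if not (-90.0 - 1e-9 <= south and self.origin_lat <= 90.0 + 1e-9):
            raise ValueError("latitude extent outside [-90, 90]")
        if not (-180.0 - 1e-9 <= self.origin_lon <= 180.0 + 1e-9):
            raise ValueError("origin_lon outside [-180, 180]")
        if self.land_mask is None:
            object.__setattr__(self, "land_mask", np.ones((self.n_rows, self.n_cols), dtype=bool))
        else:
            mask = np.asarray(self.land_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("land_mask shape does not match grid")
            object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size_deg

    @property
    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size_deg

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing (lon, lat); -1 outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size_deg).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size_deg).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def same_grid(self, other: "GridGeometry") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size_deg, other.cell_size_deg, rel_tol=0, abs_tol=1e-9)
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-9)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-9)
        )


@dataclass
class ClimateGrid:
    """Monthly climate fields, shape (12, n_rows, n_cols) each.

    tmin/tmax in deg C, rain in mm/month, rh09/rh15 in percent.
    Cells violating tmax >= tmin are removed from the land mask with a
    logged warning rather than raising.
    """

    geometry: GridGeometry
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray

    def __post_init__(self):
        shape = (12,) + self.geometry.shape
        for name in CLIMATE_VARS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        land = self.geometry.land_mask
        with np.errstate(invalid="ignore"):
            inverted = (self.tmax < self.tmin).any(axis=0) & land
            if inverted.any():
                logger.warning("masking %d cells with tmax < tmin", int(inverted.sum()))
                new_mask = land & ~inverted
                object.__setattr__(
                    self.geometry, "land_mask", new_mask
                )
            if (self.rain[:, self.geometry.land_mask] < 0).any():
                raise ValueError("negative rainfall")
            for rh_name in ("rh09", "rh15"):
                rh = getattr(self, rh_name)[:, self.geometry.land_mask]
                if ((rh < 0) | (rh > 100)).any():
                    raise ValueError(f"{rh_name} outside [0, 100]")

    @property
    def n_land(self) -> int:
        return int(self.geometry.land_mask.sum())


@dataclass(frozen=True)
class WeeklySeries:
    """One cell's 52-week climate: the engine's working currency."""

    tmin_w: np.ndarray
    tmax_w: np.ndarray
    tmean_w: np.ndarray
    rain_w: np.ndarray
    rh_w: np.ndarray

    def __post_init__(self):
        for name in ("tmin_w", "tmax_w", "tmean_w", "rain_w", "rh_w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_WEEKS,):
                raise ValueError(f"{name} must have length {N_WEEKS}")
            object.__setattr__(self, name, arr)


@dataclass
class OccurrenceSet:
    """Presence records in decimal degrees; exact duplicates removed."""

    lon: np.ndarray
    lat: np.ndarray
    source: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not self.source:
            self.source = [""] * len(self.lon)
        seen: dict[tuple[float, float], int] = {}
        keep = []
        for i, (x, y) in enumerate(zip(self.lon, self.lat)):
            if (x, y) not in seen:
                seen[(x, y)] = i
                keep.append(i)
        if len(keep) < len(self.lon):
            logger.info("dropped %d duplicate occurrence records", len(self.lon) - len(keep))
            self.lon = self.lon[keep]
            self.lat = self.lat[keep]
            self.source = [self.source[i] for i in keep]

    def __len__(self) -> int:
        return len(self.lon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lon": self.lon, "lat": self.lat, "source": self.source})


def monthly_to_weekly(
    tmin: np.ndarray,
    tmax: np.ndarray,
    rain: np.ndarray,
    rh09: np.ndarray,
    rh15: np.ndarray,
) -> WeeklySeries:
    """Convert one cell's 12 monthly values per variable to 52 weeks.

    Temperatures and humidity: periodic linear interpolation between month
    mid-points, averaged over each week's days. Rainfall: each month's total
    apportioned to overlapping weeks by overlap days, so the annual total is
    conserved exactly.
    """
    tmin = np.asarray(tmin, dtype=float)
    if tmin.shape != (12,):
        raise ValueError("expected 12 monthly values")
    tmin_w = TEMP_WEEKLY_WEIGHTS @ tmin
    tmax_w = TEMP_WEEKLY_WEIGHTS @ np.asarray(tmax, dtype=float)
    rh = (np.asarray(rh09, dtype=float) + np.asarray(rh15, dtype=float)) / 2.0
    rh_w = TEMP_WEEKLY_WEIGHTS @ rh
    rain_w = RAIN_WEEKLY_WEIGHTS @ np.asarray(rain, dtype=float)
    return WeeklySeries(tmin_w, tmax_w, (tmin_w + tmax_w) / 2.0, rain_w, rh_w)


def weekly_fields(grid: ClimateGrid) -> dict[str, np.ndarray]:
    """Weekly series for every land cell, shape (52, n_land) per variable.

    Cells are ordered by ``np.flatnonzero(land_mask)`` (row-major).
    """
    land = grid.geometry.land_mask.ravel()
    out = {}
    for name, weights in (("tmin", TEMP_WEEKLY_WEIGHTS), ("tmax", TEMP_WEEKLY_WEIGHTS)):
        monthly = getattr(grid, name).reshape(12, -1)[:, land]
        out[name + "_w"] = weights @ monthly
    rh = (grid.rh09 + grid.rh15).reshape(12, -1)[:, land] / 2.0
    out["rh_w"] = TEMP_WEEKLY_WEIGHTS @ rh
    out["rain_w"] = RAIN_WEEKLY_WEIGHTS @ grid.rain.reshape(12, -1)[:, land]
    out["tmean_w"] = (out["tmin_w"] + out["tmax_w"]) / 2.0
    return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain text; cell-centre geometry carried in header)
# ---------------------------------------------------------------------------

NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, geometry: GridGeometry) -> None:
    """Write a 2-D field as an ESRI ASCII grid; masked cells become nodata.

    Values are printed with repr-round-trip precision so read-back is
    bit-for-bit.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != geometry.shape:
        raise ValueError("values shape does not match geometry")
    out = np.where(geometry.land_mask, values, NODATA)
    yll = geometry.origin_lat - geometry.n_rows * geometry.cell_size_deg
    with open(path, "w") as fh:
        fh.write(f"ncols {geometry.n_cols}\n")
        fh.write(f"nrows {geometry.n_rows}\n")
        fh.write(f"xllcorner {geometry.origin_lon!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {geometry.cell_size_deg!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid; nodata cells are masked out of the geometry."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.vstack(rows)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} does not match header")
    nodata = header.get("nodata_value", NODATA)
    mask = values != nodata
    geometry = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_deg=header["cellsize"],
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        land_mask=mask,
    )
    return values, geometry


def write_climate_grid(directory: str | Path, grid: ClimateGrid) -> list[Path]:
    """Write one .asc per variable per month: ``<var>_<mm>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for var in CLIMATE_VARS:
        cube = getattr(grid, var)
        for m in range(12):
            p = directory / f"{var}_{m + 1:02d}.asc"
            write_ascii_grid(p, cube[m], grid.geometry)
            written.append(p)
    return written


def read_climate_grid(paths: Mapping[str, Sequence[str | Path]]) -> ClimateGrid:
    """Assemble a ClimateGrid from per-variable lists of 12 monthly rasters.

    All 60 rasters must share geometry; the land mask is the intersection of
    their data masks. Raises on a missing month or mismatched geometry,
    naming the offending variable.
    """
    cubes: dict[str, np.ndarray] = {}
    geometry: GridGeometry | None = None
    mask: np.ndarray | None = None
    for var in CLIMATE_VARS:
        if var not in paths:
            raise ValueError(f"missing variable: {var}")
        files = list(paths[var])
        if len(files) != 12:
            raise ValueError(f"{var}: expected 12 monthly rasters, got {len(files)}")
        months = []
        for p in files:
            values, geo = read_ascii_grid(p)
            if geometry is None:
                geometry = geo
                mask = geo.land_mask.copy()
            elif not geometry.same_grid(geo):
                raise ValueError(f"geometry mismatch in variable {var!r} ({p})")
            else:
                mask &= geo.land_mask
            months.append(values)
        cubes[var] = np.stack(months)
    assert geometry is not None and mask is not None
    geometry = GridGeometry(
        geometry.n_rows, geometry.n_cols, geometry.cell_size_deg,
        geometry.origin_lon, geometry.origin_lat, land_mask=mask,
    )
    return ClimateGrid(geometry=geometry, **cubes)


def read_climate_dir(directory: str | Path) -> ClimateGrid:
    """Read a directory produced by :func:`write_climate_grid`."""
    directory = Path(directory)
    paths = {
        var: [directory / f"{var}_{m + 1:02d}.asc" for m in range(12)]
        for var in CLIMATE_VARS
    }
    for var, files in paths.items():
        missing = [p.name for p in files if not p.exists()]
        if missing:
            raise ValueError(f"missing month files for {var}: {missing}")
    return read_climate_grid(paths)


def read_occurrences(path: str | Path, lon_col: str = "lon", lat_col: str = "lat") -> OccurrenceSet:
    """Load occurrences from CSV, dropping unparseable / out-of-range rows."""
    df = pd.read_csv(path)
    if lon_col not in df.columns or lat_col not in df.columns:
        raise ValueError(f"CSV must have columns {lon_col!r} and {lat_col!r}")
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d invalid occurrence rows", dropped)
    if not ok.any():
        raise ValueError("no valid occurrence records in file")
    source = df["source"].astype(str).tolist() if "source" in df.columns else []
    if source:
        source = [s for s, keep in zip(source, ok) if keep]
    return OccurrenceSet(lon[ok].to_numpy(), lat[ok].to_numpy(), source)


def write_occurrences(path: str | Path, occ: OccurrenceSet) -> None:
    occ.to_frame().to_csv(path, index=False)
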