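"""Host masking, 16-class ensemble overlay, area accounting and economics.

The two suitability tracks (mechanistic EI classes and correlative
probability classes, each 0-3) are cross-classified per cell into
id = 4*c + r, a 16-class ensemble surface, restricted to cells where at
least one host plant is predicted suitable. Areas use the spherical cell
area R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)); the economic module
multiplies a production value by a mean suitability index and a loss
coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate_io import GridGeometry

EARTH_RADIUS_KM = 6371.0088
NODATA_CLASS = 255

CLASS_LABELS = ("unsuitable", "low", "medium", "high")


def binarize_and_union_hosts(
    host_surfaces: list[np.ndarray],
    epsilon: float = 0.05,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binary host mask: 1 where any host probability exceeds ``epsilon``.

    Equivalent to binarizing each host layer and taking the union (a cell
    where the summed binaries reach 1 or more is host-suitable).
    """
    if not host_surfaces:
        raise ValueError("at least one host surface required")
    shape = np.asarray(host_surfaces[0]).shape
    out = np.zeros(shape, dtype=bool)
    for surf in host_surfaces:
        surf = np.asarray(surf, dtype=float)
        if surf.shape != shape:
            raise ValueError("host surfaces must share geometry")
        with np.errstate(invalid="ignore"):
            out |= surf > epsilon
    if mask is not None:
        out &= np.asarray(mask, dtype=bool)
    return out


def apply_host_mask(surface: np.ndarray, mask: np.ndarray, nodata=np.nan) -> np.ndarray:
    """Set cells outside the host mask to nodata; others unchanged."""
    surface = np.asarray(surface)
    mask = np.asarray(mask, dtype=bool)
    if surface.shape != mask.shape:
        raise ValueError("surface and mask must share geometry")
    if isinstance(nodata, float) and np.isnan(nodata):
        out = surface.astype(float, copy=True)
    else:
        out = surface.copy()
    out[~mask] = nodata
    return out


def cross_classify_ensemble(
    climex_levels: np.ndarray,
    rf_levels: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """16-class ensemble: id = 4*c + r per masked cell, NODATA_CLASS outside.

    c is the mechanistic (EI) level, r the correlative level, both 0-3.
    """
    c = np.asarray(climex_levels)
    r = np.asarray(rf_levels)
    mask = np.asarray(mask, dtype=bool)
    if c.shape != r.shape or c.shape != mask.shape:
        raise ValueError("inputs must share geometry")
    cm = c[mask].astype(int)
    rm = r[mask].astype(int)
    if cm.size and (cm.min() < 0 or cm.max() > 3 or rm.min() < 0 or rm.max() > 3):
        raise ValueError("suitability levels must be within 0..3")
    out = np.full(c.shape, NODATA_CLASS, dtype=np.uint8)
    out[mask] = (4 * cm + rm).astype(np.uint8)
    return out


def ensemble_legend() -> pd.DataFrame:
    """Legend mapping ensemble id -> (mechanistic label, correlative label)."""
    rows = [
        {"class_id": 4 * c + r, "climex_label": CLASS_LABELS[c], "rf_label": CLASS_LABELS[r]}
        for c in range(4)
        for r in range(4)
    ]
    return pd.DataFrame(rows)


def cell_areas_km2(geometry: GridGeometry) -> np.ndarray:
    """Spherical area of every cell, shape (n_rows, n_cols), in km^2."""
    cs = np.radians(geometry.cell_size_deg)
    lat_top = np.radians(geometry.origin_lat - np.arange(geometry.n_rows) * geometry.cell_size_deg)
    lat_bot = lat_top - np.radians(geometry.cell_size_deg)
    band = EARTH_RADIUS_KM**2 * cs * (np.sin(lat_top) - np.sin(lat_bot))
    return np.repeat(band[:, None], geometry.n_cols, axis=1)


def area_by_class(ensemble: np.ndarray, geometry: GridGeometry) -> pd.DataFrame:
    """Per-class area table over the masked (non-nodata) cells.

    Columns: class_id, n_cells, km2, pct (of the masked total). The class
    areas sum to the masked-land total and percentages to 100.
    """
    ensemble = np.asarray(ensemble)
    areas = cell_areas_km2(geometry)
    valid = ensemble != NODATA_CLASS
    total = float(areas[valid].sum())
    rows = []
    for cid in range(16):
        sel = valid & (ensemble == cid)
        km2 = float(areas[sel].sum())
        rows.append(
            {
                "class_id": cid,
                "n_cells": int(sel.sum()),
                "km2": km2,
                "pct": 100.0 * km2 / total if total > 0 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["total_km2"] = total
    return table


def suitability_change_summary(
    hist: pd.DataFrame,
    future: pd.DataFrame,
    high_classes: tuple[int, ...] = (15,),
) -> dict:
    """Per-class and aggregate change between two area tables.

    Percent change is 100 * (A_future - A_hist) / A_hist; classes with zero
    historical area report ``None`` (undefined) rather than infinity.
    Aggregates: total suitable area (every class except 0, i.e. suitable
    under at least one model) and "high" (default: high under both models,
    ensemble id 15).
    """
    if list(hist["class_id"]) != list(future["class_id"]):
        raise ValueError("area tables must share the class legend")

    def pct_change(a_h: float, a_f: float):
        if a_h == 0:
            return None
        return 100.0 * (a_f - a_h) / a_h

    per_class = []
    for (_, h), (_, f) in zip(hist.iterrows(), future.iterrows()):
        per_class.append(
            {
                "class_id": int(h["class_id"]),
                "km2_hist": h["km2"],
                "km2_future": f["km2"],
                "km2_change": f["km2"] - h["km2"],
                "pct_change": pct_change(h["km2"], f["km2"]),
            }
        )

    def agg(table: pd.DataFrame, ids) -> float:
        return float(table.loc[table["class_id"].isin(ids), "km2"].sum())

    suitable_ids = list(range(1, 16))
    h_suit, f_suit = agg(hist, suitable_ids), agg(future, suitable_ids)
    h_high, f_high = agg(hist, high_classes), agg(future, high_classes)
    return {
        "per_class": per_class,
        "total_suitable": {
            "km2_hist": h_suit,
            "km2_future": f_suit,
            "pct_change": pct_change(h_suit, f_suit),
        },
        "high_suitability": {
            "classes": list(high_classes),
            "km2_hist": h_high,
            "km2_future": f_high,
            "pct_change": pct_change(h_high, f_high),
        },
    }


def economic_loss(production_value: float, mean_suitability: float, loss_coeff: float) -> int:
    """Expected annual loss = production value x suitability x loss rate,
    rounded to the nearest integer currency unit (half away from zero)."""
    if production_value < 0 or not (0 <= mean_suitability <= 1) or not (0 <= loss_coeff <= 1):
        raise ValueError("inputs must be non-negative; rates within [0, 1]")
    loss = production_value * mean_suitability * loss_coeff
    return int(np.floor(loss + 0.5))


def mean_suitability_index(
    surface: np.ndarray,
    region_mask: np.ndarray,
    geometry: GridGeometry | None = None,
    area_weighted: bool = False,
) -> float:
    """Mean continuous suitability over a region.

    Default is the unweighted grid-cell average (a grid-to-point mean);
    ``area_weighted=True`` weights cells by their spherical area instead,
    which requires ``geometry``.
    """
    surface = np.asarray(surface, dtype=float)
    region = np.asarray(region_mask, dtype=bool) & ~np.isnan(surface)
    if not region.any():
        raise ValueError("empty region")
    if area_weighted:
        if geometry is None:
            raise ValueError("geometry required for area weighting")
        w = cell_areas_km2(geometry)[region]
        return float(np.average(surface[region], weights=w))
    return float(surface[region].mean())
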