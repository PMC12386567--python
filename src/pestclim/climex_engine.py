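"""CLIMEX-style ecoclimatic index engine.

Computes an annual Ecoclimatic Index EI in [0, 100] per grid cell from
weekly climate:

    EI = GIA x SI          (and EI = 0 if the degree-day condition fails)

where GIA = 100 x mean over weeks of TI_w x MI_w is the annual growth
index (TI, MI are trapezoidal temperature and soil-moisture responses) and
SI = (1-CS/100)(1-HS/100)(1-DS/100)(1-WS/100) is the multiplicative stress
index built from accumulated cold, heat, dry and wet stress. A cell also
needs enough degree-days above the development threshold (PDD) to complete
one generation, otherwise EI = 0.

Two implementations are provided: a vectorised grid engine
(:func:`ecoclimatic_index`) and a deliberately naive per-week scalar path
(:func:`weekly_cell_result`) kept as an independent reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .climate_io import ClimateGrid, N_WEEKS, WeeklySeries, monthly_to_weekly, weekly_fields

logger = logging.getLogger(__name__)

DAYS_PER_WEEK = 7.0

#: EI class levels: 0 unsuitable (EI = 0), 1 low (0 < EI <= 5),
#: 2 medium (5 < EI <= 12), 3 high (EI > 12).
EI_CLASS_BOUNDS = (0.0, 5.0, 12.0)
NODATA_LEVEL = 255


@dataclass(frozen=True)
class ClimexParams:
    """Species response parameters (temperature/moisture thresholds, stress
    thresholds and weekly rates, degree-day requirement) plus the soil-bucket
    engine constants.

    Temperatures in deg C; soil-moisture values as fractions of soil water
    capacity; stress rates per week (signs in published tables are direction
    markers — magnitudes are used); PDD in deg C days.
    """

    DV0: float
    DV1: float
    DV2: float
    DV3: float
    SM0: float
    SM1: float
    SM2: float
    SM3: float
    TTCS: float
    THCS: float
    TTHS: float
    THHS: float
    SMDS: float
    HDS: float
    SMWS: float
    HWS: float
    PDD: float
    # Engine constants for the soil-moisture bucket. sm_cap is the bucket
    # ceiling as a fraction of capacity: extra rain runs off above it.
    soil_capacity_mm: float = 100.0
    evap_coeff: float = 0.8
    sm_cap: float = 1.0

    def __post_init__(self):
        if not (self.DV0 < self.DV1 <= self.DV2 < self.DV3):
            raise ValueError("need DV0 < DV1 <= DV2 < DV3")
        if not (self.SM0 < self.SM1 <= self.SM2 < self.SM3):
            raise ValueError("need SM0 < SM1 <= SM2 < SM3")
        if self.TTHS < self.DV3:
            raise ValueError("heat-stress threshold TTHS must be >= DV3")
        if self.SMDS > self.SM0:
            raise ValueError("dry-stress threshold SMDS must be <= SM0")
        if self.PDD < 0:
            raise ValueError("PDD must be non-negative")
        if self.soil_capacity_mm <= 0 or self.evap_coeff < 0 or self.sm_cap <= 0:
            raise ValueError("invalid soil bucket constants")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "ClimexParams":
        """Read a flat ``KEY = value`` parameter file (# comments allowed)."""
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
        values.update(overrides)
        return cls(**values)

    def replace(self, **changes) -> "ClimexParams":
        return replace(self, **changes)


def load_default_params(**overrides) -> ClimexParams:
    """The shipped pepper weevil (*Anthonomus eugenii*) parameter set."""
    from importlib.resources import files

    return ClimexParams.from_file(
        files("pestclim.data") / "anthonomus_eugenii.params", **overrides
    )


def trapezoid(x: np.ndarray, lo: float, opt_lo: float, opt_hi: float, hi: float) -> np.ndarray:
    """Piecewise-linear response: 0 outside (lo, hi), 1 on [opt_lo, opt_hi]."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if opt_lo > lo:
        rising = (x > lo) & (x < opt_lo)
        out[rising] = (x[rising] - lo) / (opt_lo - lo)
    out[(x >= opt_lo) & (x <= opt_hi)] = 1.0
    if hi > opt_hi:
        falling = (x > opt_hi) & (x < hi)
        out[falling] = (hi - x[falling]) / (hi - opt_hi)
    return out


def temperature_index(tmean_w: np.ndarray, params: ClimexParams) -> np.ndarray:
    """Weekly temperature index TI in [0, 1] (trapezoid over DV0..DV3)."""
    return trapezoid(tmean_w, params.DV0, params.DV1, params.DV2, params.DV3)


def moisture_index(sm_w: np.ndarray, params: ClimexParams) -> np.ndarray:
    """Weekly moisture index MI in [0, 1] (trapezoid over SM0..SM3)."""
    return trapezoid(sm_w, params.SM0, params.SM1, params.SM2, params.SM3)


def soil_moisture_series(
    rain_w: np.ndarray,
    tmean_w: np.ndarray,
    rh_w: np.ndarray,
    params: ClimexParams,
    sm_init: float = 0.5,
    min_cycles: int = 3,
    max_cycles: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Weekly soil moisture (fraction of capacity) from a bucket model.

    SM_{t+1} = clip(SM_t + (rain_t - E_t) / capacity, 0, sm_cap) with
    evapotranspiration E_t = evap_coeff * max(0, tmean_t) * (1 - rh_t/100).
    The year is cycled from SM = ``sm_init`` until the weekly trajectory is
    periodic (max change <= tol), at least ``min_cycles`` and at most
    ``max_cycles`` years; the final year is returned.

    Accepts (52,) series for one cell or (52, n) stacks for many.
    """
    rain_w = np.atleast_1d(np.asarray(rain_w, dtype=float))
    tmean_w = np.asarray(tmean_w, dtype=float)
    rh_w = np.asarray(rh_w, dtype=float)
    evap = params.evap_coeff * np.maximum(0.0, tmean_w) * (1.0 - rh_w / 100.0)
    delta = (rain_w - evap) / params.soil_capacity_mm

    sm = np.full(rain_w.shape[1:] if rain_w.ndim > 1 else (), sm_init, dtype=float)
    trace = np.empty_like(delta)
    prev = None
    for cycle in range(max_cycles):
        for t in range(N_WEEKS):
            sm = np.clip(sm + delta[t], 0.0, params.sm_cap)
            trace[t] = sm
        if prev is not None and cycle + 1 >= min_cycles:
            if np.max(np.abs(trace - prev)) <= tol:
                return trace.copy()
        prev = trace.copy()
    warnings.warn("soil-moisture bucket did not reach a periodic steady state", RuntimeWarning)
    return trace.copy()


def growth_index_annual(ti_w: np.ndarray, mi_w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weekly growth index GI = TI x MI and annual GIA = 100 x mean(GI)."""
    gi = np.asarray(ti_w, dtype=float) * np.asarray(mi_w, dtype=float)
    return gi, 100.0 * gi.mean(axis=0)


def accumulate_stresses(
    tmin_w: np.ndarray,
    tmax_w: np.ndarray,
    sm_w: np.ndarray,
    params: ClimexParams,
) -> dict[str, np.ndarray]:
    """Annual cold/heat/dry/wet stress and the stress index SI.

    Each stress accumulates linearly over the year:
    S = min(100, 100 * |rate| * sum_w excess_w), with the excess being how
    far the week's driver crosses the stress threshold (tmin below TTCS for
    cold, tmax above TTHS for heat, soil moisture below SMDS / above SMWS
    for dry / wet). SI multiplies the four survival factors.
    """
    cs = 100.0 * abs(params.THCS) * np.maximum(0.0, params.TTCS - tmin_w).sum(axis=0)
    hs = 100.0 * abs(params.THHS) * np.maximum(0.0, tmax_w - params.TTHS).sum(axis=0)
    ds = 100.0 * abs(params.HDS) * np.maximum(0.0, params.SMDS - sm_w).sum(axis=0)
    ws = 100.0 * abs(params.HWS) * np.maximum(0.0, sm_w - params.SMWS).sum(axis=0)
    cs, hs, ds, ws = (np.minimum(100.0, s) for s in (cs, hs, ds, ws))
    si = (1 - cs / 100.0) * (1 - hs / 100.0) * (1 - ds / 100.0) * (1 - ws / 100.0)
    return {"CS": cs, "HS": hs, "DS": ds, "WS": ws, "SI": si}


def degree_days_check(tmean_w: np.ndarray, params: ClimexParams) -> tuple[np.ndarray, np.ndarray]:
    """Annual degree-days above DV0 (7 days/week) and whether PDD is met."""
    dd = DAYS_PER_WEEK * np.maximum(0.0, np.asarray(tmean_w, dtype=float) - params.DV0).sum(axis=0)
    return dd, dd >= params.PDD


@dataclass(frozen=True)
class EcoclimaticResult:
    """Per-cell annual summary of the mechanistic model."""

    gi_w: np.ndarray
    GIA: float
    CS: float
    HS: float
    DS: float
    WS: float
    SI: float
    dd_annual: float
    pdd_met: bool
    EI: float


def weekly_cell_result(
    series: WeeklySeries,
    params: ClimexParams,
    sm_w: np.ndarray | None = None,
) -> EcoclimaticResult:
    """Naive scalar reference: straight per-week loops, no vectorisation.

    ``sm_w`` pins the soil-moisture series directly (bypassing the bucket),
    which is how controlled-moisture scenarios are expressed.
    """
    if sm_w is None:
        sm_w = soil_moisture_series(series.rain_w, series.tmean_w, series.rh_w, params)
    sm_w = np.asarray(sm_w, dtype=float)

    gi_w = np.zeros(N_WEEKS)
    cs = hs = ds = ws = dd = 0.0
    for t in range(N_WEEKS):
        ti = float(trapezoid(series.tmean_w[t], params.DV0, params.DV1, params.DV2, params.DV3))
        mi = float(trapezoid(sm_w[t], params.SM0, params.SM1, params.SM2, params.SM3))
        gi_w[t] = ti * mi
        cs += max(0.0, params.TTCS - series.tmin_w[t])
        hs += max(0.0, series.tmax_w[t] - params.TTHS)
        ds += max(0.0, params.SMDS - sm_w[t])
        ws += max(0.0, sm_w[t] - params.SMWS)
        dd += max(0.0, series.tmean_w[t] - params.DV0) * DAYS_PER_WEEK
    CS = min(100.0, 100.0 * abs(params.THCS) * cs)
    HS = min(100.0, 100.0 * abs(params.THHS) * hs)
    DS = min(100.0, 100.0 * abs(params.HDS) * ds)
    WS = min(100.0, 100.0 * abs(params.HWS) * ws)
    SI = (1 - CS / 100.0) * (1 - HS / 100.0) * (1 - DS / 100.0) * (1 - WS / 100.0)
    GIA = 100.0 * gi_w.mean()
    pdd_met = dd >= params.PDD
    EI = GIA * SI if pdd_met else 0.0
    return EcoclimaticResult(gi_w, GIA, CS, HS, DS, WS, SI, dd, bool(pdd_met), EI)


@dataclass
class EngineResult:
    """Gridded engine output; 2-D arrays are NaN outside the land mask."""

    EI: np.ndarray
    GIA: np.ndarray
    CS: np.ndarray
    HS: np.ndarray
    DS: np.ndarray
    WS: np.ndarray
    SI: np.ndarray
    dd_annual: np.ndarray
    pdd_met: np.ndarray  # boolean, False off-mask
    mask: np.ndarray


def ecoclimatic_index(
    grid: ClimateGrid,
    params: ClimexParams,
    sm_override: np.ndarray | None = None,
) -> EngineResult:
    """Vectorised EI over all land cells of a climate grid.

    ``sm_override``: optional (52, n_land) soil-moisture stack replacing the
    bucket model.
    """
    mask = grid.geometry.land_mask
    wf = weekly_fields(grid)
    if sm_override is None:
        sm = soil_moisture_series(wf["rain_w"], wf["tmean_w"], wf["rh_w"], params)
    else:
        sm = np.asarray(sm_override, dtype=float)

    ti = temperature_index(wf["tmean_w"], params)
    mi = moisture_index(sm, params)
    _, gia = growth_index_annual(ti, mi)
    stresses = accumulate_stresses(wf["tmin_w"], wf["tmax_w"], sm, params)
    dd, pdd_met = degree_days_check(wf["tmean_w"], params)
    ei = np.where(pdd_met, gia * stresses["SI"], 0.0)

    n_pdd_failed = int((~pdd_met).sum())
    if n_pdd_failed:
        logger.info("%d land cells fail the degree-day condition", n_pdd_failed)

    def expand(flat, fill=np.nan):
        full = np.full(mask.shape, fill, dtype=float)
        full[mask] = flat
        return full

    pdd_full = np.zeros(mask.shape, dtype=bool)
    pdd_full[mask] = pdd_met
    return EngineResult(
        EI=expand(ei),
        GIA=expand(gia),
        CS=expand(stresses["CS"]),
        HS=expand(stresses["HS"]),
        DS=expand(stresses["DS"]),
        WS=expand(stresses["WS"]),
        SI=expand(stresses["SI"]),
        dd_annual=expand(dd),
        pdd_met=pdd_full,
        mask=mask,
    )


def ecoclimatic_index_reference(grid: ClimateGrid, params: ClimexParams) -> np.ndarray:
    """Per-cell naive loop over the same grid; EI array, NaN off-mask."""
    mask = grid.geometry.land_mask
    out = np.full(mask.shape, np.nan)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            series = monthly_to_weekly(
                grid.tmin[:, r, c], grid.tmax[:, r, c], grid.rain[:, r, c],
                grid.rh09[:, r, c], grid.rh15[:, r, c],
            )
            out[r, c] = weekly_cell_result(series, params).EI
    return out


def classify_ei(ei: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Four-level suitability classes from EI.

    0 unsuitable (EI = 0), 1 low (0 < EI <= 5), 2 medium (5 < EI <= 12),
    3 high (EI > 12); NODATA_LEVEL (255) outside the mask.
    """
    ei = np.asarray(ei, dtype=float)
    levels = np.zeros(ei.shape, dtype=np.uint8)
    levels[ei > EI_CLASS_BOUNDS[0]] = 1
    levels[ei > EI_CLASS_BOUNDS[1]] = 2
    levels[ei > EI_CLASS_BOUNDS[2]] = 3
    if mask is None:
        mask = ~np.isnan(ei)
    levels[~mask] = NODATA_LEVEL
    return levels
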