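"""Seeded synthetic climate worlds and virtual species.

The generator produces climate grids with the gross structure of real
monthly climatologies — temperature falling with latitude, seasonal cycles
in antiphase between hemispheres, wetter tropics, plausible humidity — so
every pipeline stage can be exercised and validated without downloading
climate layers. A virtual species is a known product-of-trapezoids response
to bioclimatic summaries; sampling it yields occurrence records whose true
suitability is known everywhere, the standard device for validating
distribution models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .climate_io import ClimateGrid, GridGeometry, OccurrenceSet
from .correlative_sdm import BIOCLIM_NAMES, bioclim_variables

#: Default virtual species: a warm, humid-climate specialist limited by
#: warmest-month maximum temperature and annual rainfall. The niche is
#: deliberately narrow (suitable on roughly a fifth of the default world's
#: land), matching the restricted tropical/subtropical distributions of the
#: insect pests this pipeline targets.
DEFAULT_RESPONSES: dict[str, tuple[float, float, float, float]] = {
    "bio5": (23.0, 28.0, 30.5, 33.0),
    "bio12": (850.0, 1100.0, 1350.0, 1650.0),
}


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Parameters of a synthetic climate world.

    Temperature: monthly mean ``t_eq - lapse*|lat| + A(lat)*cos(phase)``
    where the seasonal amplitude grows linearly from 0 at the equator to
    ``seasonal_amplitude`` at the poles and the phase peaks in July (north)
    or January (south). tmin/tmax sit ``diurnal_half_range`` below/above the
    mean. Rainfall: annual total scaled by latitude (wet tropics, weight
    ``rain_lat_gradient``) and modulated along longitude by a
    ``continentality`` harmonic (``lon_waves`` wet/dry belts, emulating
    maritime versus continental interiors), spread over months with a
    wet-season cosine of weight ``wet_season_concentration``. Humidity: a
    base level with seeded Gaussian noise, 09:00 a little moister than
    15:00.
    ``warming_offset_c`` shifts all temperatures uniformly, emulating a
    future scenario.
    """

    n_rows: int = 90
    n_cols: int = 180
    cell_size_deg: float = 2.0
    t_eq: float = 28.0
    lapse_per_deg: float = 0.6
    seasonal_amplitude: float = 18.0
    diurnal_half_range: float = 5.0
    annual_rain_mm: float = 1100.0
    rain_lat_gradient: float = 0.75
    continentality: float = 0.4
    lon_waves: int = 2
    wet_season_concentration: float = 0.8
    rh_base: float = 70.0
    rh_noise_sd: float = 5.0
    warming_offset_c: float = 0.0
    continents: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.seasonal_amplitude < 0 or self.annual_rain_mm < 0:
            raise ValueError("amplitude and annual rain must be non-negative")
        if not (0 <= self.wet_season_concentration < 1):
            raise ValueError("wet_season_concentration must be in [0, 1)")
        if not (0 <= self.continentality < 1) or not (0 <= self.rain_lat_gradient <= 1):
            raise ValueError("continentality in [0, 1), rain_lat_gradient in [0, 1]")

    def warmed(self, offset_c: float) -> "SyntheticWorldSpec":
        return replace(self, warming_offset_c=self.warming_offset_c + offset_c)


def _continent_mask(n_rows: int, n_cols: int, seed: int) -> np.ndarray:
    """Procedural land mask from smooth low-frequency bumps (~60% land)."""
    rng = np.random.default_rng(seed + 7_654_321)
    y, x = np.mgrid[0:n_rows, 0:n_cols]
    fy, fx = y / n_rows, x / n_cols
    z = np.zeros((n_rows, n_cols))
    for _ in range(6):
        ay, ax, py, px = rng.uniform(1, 3, 2).tolist() + rng.uniform(0, 2 * np.pi, 2).tolist()
        z += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * ay * fy + py) * np.cos(2 * np.pi * ax * fx + px)
    return z > np.quantile(z, 0.4)


def generate_climate_grid(spec: SyntheticWorldSpec) -> ClimateGrid:
    """Deterministic synthetic climate world for a spec (same spec + seed
    always gives the identical grid)."""
    mask = (
        _continent_mask(spec.n_rows, spec.n_cols, spec.seed) if spec.continents else None
    )
    geometry = GridGeometry(
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
        cell_size_deg=spec.cell_size_deg,
        origin_lon=-180.0,
        origin_lat=min(90.0, spec.n_rows * spec.cell_size_deg / 2.0),
        land_mask=mask,
    )
    lat = geometry.lat_centers[:, None]  # (rows, 1), broadcast over columns
    months = np.arange(12)

    amp = spec.seasonal_amplitude * np.abs(lat) / 90.0
    peak = np.where(lat >= 0, 6.0, 0.0)  # July north, January south
    phase = np.cos(2 * np.pi * (months[:, None, None] - peak[None]) / 12.0)
    tmean = spec.t_eq - spec.lapse_per_deg * np.abs(lat)[None] + amp[None] * phase
    tmean = tmean + spec.warming_offset_c
    tmean = np.broadcast_to(tmean, (12, spec.n_rows, spec.n_cols)).copy()
    tmin = tmean - spec.diurnal_half_range
    tmax = tmean + spec.diurnal_half_range

    g = spec.rain_lat_gradient
    lon = geometry.lon_centers[None, :]
    zonal = (1.0 - g) + g * np.cos(np.radians(lat))
    belts = 1.0 + spec.continentality * np.sin(np.radians(spec.lon_waves * lon))
    annual = spec.annual_rain_mm * zonal * belts
    wet = 1.0 + spec.wet_season_concentration * phase  # wet season in summer
    rain = np.broadcast_to(annual[None] / 12.0 * wet, (12, spec.n_rows, spec.n_cols)).copy()

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.rh_noise_sd, size=(12, spec.n_rows, spec.n_cols))
    rh09 = np.clip(spec.rh_base + 5.0 + noise, 5.0, 100.0)
    rh15 = np.clip(spec.rh_base - 5.0 + noise, 5.0, 100.0)

    return ClimateGrid(geometry=geometry, tmin=tmin, tmax=tmax, rain=rain, rh09=rh09, rh15=rh15)


@dataclass
class VirtualSpeciesTruth:
    """Known suitability of a virtual species, rescaled to max 1 on land."""

    truth: np.ndarray  # (rows, cols), 0 off-mask
    responses: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    geometry: GridGeometry | None = None


def virtual_species_truth(
    grid: ClimateGrid,
    responses: dict[str, tuple[float, float, float, float]] | None = None,
) -> VirtualSpeciesTruth:
    """Product of trapezoid responses over named bioclim summaries.

    Raises if the species is nowhere viable in this world (truth all zero):
    such a world cannot support sampling and should be regenerated.
    """
    from .climex_engine import trapezoid

    responses = dict(DEFAULT_RESPONSES if responses is None else responses)
    bio = bioclim_variables(grid)
    mask = grid.geometry.land_mask
    truth = np.ones(grid.geometry.shape)
    for name, (lo, b, c, hi) in responses.items():
        idx = BIOCLIM_NAMES.index(name)
        truth *= trapezoid(bio[..., idx], lo, b, c, hi)
    truth[~mask] = 0.0
    peak = truth.max()
    if peak <= 0:
        raise ValueError("virtual species has zero suitability everywhere in this world")
    return VirtualSpeciesTruth(truth / peak, responses, grid.geometry)


def sample_occurrences(
    truth: VirtualSpeciesTruth,
    n: int,
    sampling_bias: np.ndarray | None = None,
    seed: int = 0,
    replace: bool = True,
) -> OccurrenceSet:
    """Draw occurrence records with probability proportional to truth.

    Cells are drawn (with replacement by default; several records may share
    a cell, as in real databases) and each record is jittered uniformly
    within its cell. ``sampling_bias`` multiplies the sampling weights to
    emulate uneven survey effort.
    """
    geometry = truth.geometry
    if geometry is None:
        raise ValueError("truth must carry its grid geometry")
    w = truth.truth.astype(float).copy()
    if sampling_bias is not None:
        w = w * np.asarray(sampling_bias, dtype=float)
    w = w.ravel()
    w[~np.isfinite(w)] = 0.0
    support = int((w > 0).sum())
    if support == 0:
        raise ValueError("no cell has positive sampling weight")
    if not replace and n > support:
        raise ValueError(f"cannot draw {n} distinct cells from a support of {support}")
    rng = np.random.default_rng(seed)
    cells = rng.choice(w.size, size=n, replace=replace, p=w / w.sum())
    rows, cols = np.divmod(cells, geometry.n_cols)
    jitter_lon = rng.uniform(0.0, geometry.cell_size_deg, size=n)
    jitter_lat = rng.uniform(0.0, geometry.cell_size_deg, size=n)
    lon = geometry.origin_lon + cols * geometry.cell_size_deg + jitter_lon
    lat = geometry.origin_lat - rows * geometry.cell_size_deg - jitter_lat
    return OccurrenceSet(lon, lat, ["synthetic"] * n)
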