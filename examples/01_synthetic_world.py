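"""Generate the default synthetic climate world and describe it.

The world is a 90x180 grid at 2 degrees with latitudinal temperature
structure, hemisphere-antiphase seasons, wetter tropics with longitudinal
wet/dry belts, and seeded humidity noise.
"""

import numpy as np

from pestclim import SyntheticWorldSpec, generate_climate_grid, virtual_species_truth

spec = SyntheticWorldSpec(seed=42)
grid = generate_climate_grid(spec)
lat = grid.geometry.lat_centers

eq = np.argmin(np.abs(lat))
print(f"grid: {grid.geometry.n_rows}x{grid.geometry.n_cols} cells at {spec.cell_size_deg} deg")
print(f"equatorial annual-mean tmax: {grid.tmax[:, eq, :].mean():.1f} C")
print(f"polar-row annual-mean tmax:  {grid.tmax[:, 0, :].mean():.1f} C")
print(f"annual rain, equator row: {grid.rain[:, eq, :].sum(axis=0).mean():.0f} mm "
      f"(range {grid.rain[:, eq, :].sum(axis=0).min():.0f}-{grid.rain[:, eq, :].sum(axis=0).max():.0f} across longitudes)")

truth = virtual_species_truth(grid)
frac = (truth.truth > 0).mean()
print(f"default virtual species occupies {100 * frac:.1f}% of the world "
      "(a warm-humid specialist: suitability falls to zero outside its "
      "warmest-month-temperature and annual-rainfall envelope)")
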