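"""Cross-classify the two suitability tracks under a host mask and account
areas and potential economic loss.

Each cell gets an ensemble id 4*c + r from its mechanistic level c and
correlative level r (both 0-3), restricted to cells where at least one host
is predicted suitable; areas use spherical cell geometry.
"""

import numpy as np

from pestclim import (
    SyntheticWorldSpec,
    area_by_class,
    apply_host_mask,
    binarize_and_union_hosts,
    build_training_table,
    classify_ei,
    classify_probability_surface,
    cross_classify_ensemble,
    economic_loss,
    ecoclimatic_index,
    fit_and_cross_validate,
    generate_climate_grid,
    load_default_params,
    mean_suitability_index,
    rarefy_occurrences,
    sample_occurrences,
    virtual_species_truth,
)
from pestclim.correlative_sdm import predict_probability_surface
from pestclim.pipeline import HOST_RESPONSES

grid = generate_climate_grid(SyntheticWorldSpec(seed=42))
mask = grid.geometry.land_mask

# correlative track (pest)
truth = virtual_species_truth(grid)
occ = rarefy_occurrences(sample_occurrences(truth, 300, seed=1), 10.0)
table = build_training_table(grid, occ, seed=1)
model, _ = fit_and_cross_validate(table, seed=1, n_estimators=100)
p_pest = predict_probability_surface(model, grid)
rf_levels = classify_probability_surface(p_pest, mask)

# mechanistic track
res = ecoclimatic_index(grid, load_default_params())
climex_levels = classify_ei(res.EI, res.mask)

# host mask from two virtual host plants (broader niches than the pest)
host_surfaces = [virtual_species_truth(grid, r).truth for r in HOST_RESPONSES.values()]
host_mask = binarize_and_union_hosts(host_surfaces, epsilon=0.05, mask=mask)

ensemble = cross_classify_ensemble(climex_levels, rf_levels, host_mask)
areas = area_by_class(ensemble, grid.geometry)
suitable = areas.loc[areas.class_id > 0, "pct"].sum()
print(f"host-suitable cells: {host_mask.sum()} of {mask.sum()} land cells")
print(f"suitable under at least one model: {suitable:.1f}% of host-masked land")
print(f"high under both models (id 15): {areas.loc[15, 'pct']:.2f}%")

mean_s = mean_suitability_index(apply_host_mask(p_pest, host_mask), host_mask)
loss = economic_loss(799, mean_s, 0.612)
print(f"mean suitability over the host range: {mean_s:.3f}")
print(f"potential annual loss at a 799-unit production value and 0.612 loss rate: {loss} units")
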