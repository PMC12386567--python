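# pestclim

Two-track climatic risk mapping for invasive insect pests, built around the
pepper weevil / chili pepper system but parameterizable for any species. The
package pairs a **mechanistic ecoclimatic-index engine** (a CLIMEX-style
growth-and-stress model on a weekly time step) with a **correlative
presence/background classifier** (random forest on the 19 bioclim
predictors), then overlays the two host-masked suitability maps into a
16-class ensemble with spherical area accounting and a potential
economic-loss estimate. Everything runs on seeded synthetic climate worlds
and virtual species with known responses, so the whole pipeline is testable
without downloading climate layers or occurrence databases.

It is aimed at quantitative ecologists and plant-protection analysts who
want the *method* — reproducible, inspectable, unit-tested — rather than a
GIS workflow.

## The models

**Mechanistic track.** Per grid cell and week, trapezoidal responses give a
temperature index TI (thresholds DV0 < DV1 ≤ DV2 < DV3) and a moisture
index MI (SM0 < SM1 ≤ SM2 < SM3, as fractions of soil water capacity, with
soil moisture from a weekly bucket model). Annually,

    GIA = 100 · mean_w(TI_w · MI_w)
    SI  = (1 − CS/100)(1 − HS/100)(1 − DS/100)(1 − WS/100)
    EI  = GIA · SI        (EI = 0 if annual degree-days above DV0 < PDD)

where each stress (cold, heat, dry, wet) accumulates linearly as
100 · |rate| · Σ_w threshold-excess, capped at 100. EI ∈ [0, 100] is
classified 0 / (0, 5] / (5, 12] / > 12 into unsuitable, low, medium and
high suitability. The shipped parameter file carries the pepper-weevil
values (DV0 = 9.6 °C, PDD = 256.4 °C·days, cold stress below −10 °C, ...).

**Correlative track.** Occurrences are spatially rarefied (10 km default),
background cells drawn at 4× the presence count outside an exclusion
buffer, and a bagged-tree classifier is scored by stratified 10-fold
cross-validation: AUC (Mann–Whitney form), Cohen's kappa and the true skill
statistic TSS = sensitivity + specificity − 1 at the max-TSS threshold.
The probability surface is classified into four levels by exact
Fisher–Jenks natural breaks.

**Ensemble.** Cells where at least one host plant is predicted suitable are
kept; each keeps a class id 4·c + r from its mechanistic level c and
correlative level r. Areas use R²Δλ(sin φ_top − sin φ_bot) per cell;
potential loss = production value × mean suitability × loss coefficient.

## Worked example

```bash
python examples/03_correlative_sdm.py
```

```
training table: 283 presences + 1132 background rows
10-fold CV: AUC 0.921, kappa 0.667, TSS 0.828
(adequate discrimination is AUC >= 0.85, kappa >= 0.6, TSS >= 0.6)
```

300 virtual-species records thin to 283 occupied cells; held-out AUC 0.921
means a randomly chosen presence cell outranks a random background cell 92%
of the time, and all three statistics clear the conventional adequacy bar.
`examples/04_ensemble_overlay.py` continues to the host-masked overlay:

```
host-suitable cells: 9360 of 16200 land cells
suitable under at least one model: 78.1% of host-masked land
high under both models (id 15): 8.89%
mean suitability over the host range: 0.159
potential annual loss at a 799-unit production value and 0.612 loss rate: 78 units
```

The other examples cover world generation, the mechanistic engine (range
limits set by degree-day accumulation; a +4 °C world shifts them poleward)
and the one-call pipeline with its reproducibility manifest. The `pestclim`
console command exposes the same stages (`synth`, `climex`, `sdm`,
`ensemble`, `run`).

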