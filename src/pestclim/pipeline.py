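"""End-to-end orchestration of the two-track risk-mapping workflow.

One call runs: correlative fits for the pest and its host plants ->
mechanistic ecoclimatic index -> host mask -> masked extraction ->
16-class ensemble overlay -> area accounting, scenario change report and
the economic-loss estimate. All randomness flows from one root seed; a
manifest of config, seeds, versions and output hashes makes reruns
bit-for-bit checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import sklearn

from . import __version__
from .climate_io import write_ascii_grid, write_climate_grid, write_occurrences
from .climex_engine import classify_ei, ecoclimatic_index, load_default_params
from .correlative_sdm import (
    build_training_table,
    classify_probability_surface,
    fit_and_cross_validate,
    permutation_importance,
    predict_probability_surface,
    rarefy_occurrences,
)
from .hosts_ensemble import (
    apply_host_mask,
    area_by_class,
    binarize_and_union_hosts,
    cross_classify_ensemble,
    economic_loss,
    ensemble_legend,
    mean_suitability_index,
    suitability_change_summary,
)
from .synthetic_data import (
    SyntheticWorldSpec,
    generate_climate_grid,
    sample_occurrences,
    virtual_species_truth,
)

logger = logging.getLogger(__name__)

#: Virtual host plants: broader climatic tolerances than the pest.
HOST_RESPONSES = {
    "host_a": {"bio5": (12.0, 20.0, 34.0, 38.0), "bio12": (250.0, 500.0, 1800.0, 2800.0)},
    "host_b": {"bio5": (15.0, 22.0, 33.0, 37.0), "bio12": (200.0, 600.0, 2000.0, 3000.0)},
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see field defaults for the knobs."""

    out_dir: str
    world: SyntheticWorldSpec = field(default_factory=SyntheticWorldSpec)
    scenarios: dict[str, float] = field(default_factory=lambda: {"baseline": 0.0, "warm4": 4.0})
    n_occurrences: int = 300
    n_host_occurrences: int = 300
    radius_km: float = 10.0
    ratio: int = 4
    folds: int = 10
    train_frac: float = 0.7
    epsilon: float = 0.05
    n_estimators: int = 200
    production_value: float = 799.0
    loss_coeff: float = 0.612
    seed: int = 42

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Stage failures abort with the stage name; outputs written so far are
    left in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    results: dict = {"scenarios": {}}
    try:
        stage = "synthetic-world"
        t0 = time.time()
        base_spec = dataclasses.replace(config.world, seed=config.stage_seed("world"))
        base_grid = generate_climate_grid(base_spec)
        logger.info("world %s cells in %.1fs", base_grid.geometry.shape, time.time() - t0)

        stage = "virtual-species"
        pest_truth = virtual_species_truth(base_grid)
        occ = sample_occurrences(pest_truth, config.n_occurrences, seed=config.stage_seed("occ"))
        occ = rarefy_occurrences(occ, config.radius_km)
        write_occurrences(out / "occurrences.csv", occ)

        stage = "correlative-fit-pest"
        table = build_training_table(
            base_grid, occ, ratio=config.ratio,
            exclusion_km=config.radius_km, seed=config.stage_seed("background"),
        )
        model, report = fit_and_cross_validate(
            table, k_folds=config.folds, train_frac=config.train_frac,
            seed=config.stage_seed("cv"), n_estimators=config.n_estimators,
        )
        importance = permutation_importance(model, table, seed=config.stage_seed("imp"))
        importance.rename("contribution_pct").to_csv(out / "importance.csv")
        results["pest_cv"] = {
            "auc": report.auc, "kappa": report.kappa, "tss": report.tss,
            "n_presence": int(table["label"].sum()), "n_rows": len(table),
        }

        stage = "correlative-fit-hosts"
        host_models = {}
        for name, resp in HOST_RESPONSES.items():
            h_truth = virtual_species_truth(base_grid, resp)
            h_occ = sample_occurrences(
                h_truth, config.n_host_occurrences, seed=config.stage_seed(f"occ-{name}")
            )
            h_occ = rarefy_occurrences(h_occ, config.radius_km)
            h_table = build_training_table(
                base_grid, h_occ, ratio=config.ratio,
                exclusion_km=config.radius_km, seed=config.stage_seed(f"background-{name}"),
            )
            h_model, h_report = fit_and_cross_validate(
                h_table, k_folds=config.folds, train_frac=config.train_frac,
                seed=config.stage_seed(f"cv-{name}"), n_estimators=config.n_estimators,
            )
            host_models[name] = h_model
            results.setdefault("host_cv", {})[name] = {
                "auc": h_report.auc, "kappa": h_report.kappa, "tss": h_report.tss,
            }

        params = load_default_params()
        area_tables = {}
        for label, offset in config.scenarios.items():
            stage = f"scenario-{label}"
            spec = base_spec.warmed(offset)
            grid = base_grid if offset == 0 else generate_climate_grid(spec)
            sdir = out / label
            sdir.mkdir(exist_ok=True)
            write_climate_grid(sdir / "climate", grid)

            p_pest = predict_probability_surface(model, grid)
            occ_rows, occ_cols = grid.geometry.cell_of(occ.lon, occ.lat)
            on_grid = occ_rows >= 0
            occ_p = p_pest[occ_rows[on_grid], occ_cols[on_grid]]
            rf_levels = classify_probability_surface(
                p_pest, grid.geometry.land_mask, occurrence_p=occ_p, epsilon=config.epsilon
            )

            engine = ecoclimatic_index(grid, params)
            climex_levels = classify_ei(engine.EI, engine.mask)

            host_surfaces = [
                predict_probability_surface(m, grid) for m in host_models.values()
            ]
            host_mask = binarize_and_union_hosts(
                host_surfaces, epsilon=config.epsilon, mask=grid.geometry.land_mask
            )
            ensemble = cross_classify_ensemble(climex_levels, rf_levels, host_mask)
            areas = area_by_class(ensemble, grid.geometry)
            area_tables[label] = areas

            write_ascii_grid(sdir / "ei.asc", np.nan_to_num(engine.EI, nan=-9999.0), grid.geometry)
            write_ascii_grid(sdir / "rf_prob.asc", np.nan_to_num(p_pest, nan=-9999.0), grid.geometry)
            write_ascii_grid(sdir / "ensemble.asc", ensemble.astype(float), grid.geometry)
            areas.to_csv(sdir / "areas.csv", index=False)

            masked_p = apply_host_mask(p_pest, host_mask)
            mean_suit = mean_suitability_index(masked_p, host_mask)
            results["scenarios"][label] = {
                "warming_offset_c": offset,
                "mean_suitability": mean_suit,
                "economic_loss": economic_loss(
                    config.production_value, mean_suit, config.loss_coeff
                ),
                "total_land_km2": areas.attrs["total_km2"],
                "n_host_cells": int(host_mask.sum()),
            }

        stage = "change-report"
        baseline_label = next(iter(config.scenarios))
        for label in config.scenarios:
            if label == baseline_label:
                continue
            results.setdefault("change", {})[label] = suitability_change_summary(
                area_tables[baseline_label], area_tables[label]
            )
        ensemble_legend().to_csv(out / "legend.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))
    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "world"},
            "world": dataclasses.asdict(config.world),
        },
        "versions": {
            "pestclim": __version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
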