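import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from pestclim.climate_io import GridGeometry, OccurrenceSet
from pestclim.correlative_sdm import (
    auc_mann_whitney,
    bioclim_variables,
    build_training_table,
    classify_probability_surface,
    compute_metrics,
    fit_and_cross_validate,
    haversine_km,
    jenks_breaks,
    metrics_from_confusion,
    permutation_importance,
    rarefy_occurrences,
    sample_pseudo_absences,
)
from conftest import random_climate_grid


class TestRarefaction:
    def test_pair_within_radius_thins_to_one(self):
        # ~5 km apart (0.045 deg of latitude)
        occ = OccurrenceSet(np.array([10.0, 10.0]), np.array([50.0, 50.045]))
        assert len(rarefy_occurrences(occ, 10.0)) == 1

    def test_pair_outside_radius_both_kept(self):
        occ = OccurrenceSet(np.array([10.0, 10.0]), np.array([50.0, 50.135]))  # ~15 km
        assert len(rarefy_occurrences(occ, 10.0)) == 2

    def test_lattice_matches_bruteforce_greedy_oracle(self):
        # 100 points on a ~1 km lattice
        step = 1.0 / 111.19  # ~1 km in degrees latitude
        lats, lons = np.meshgrid(np.arange(10) * step, np.arange(10) * step)
        occ = OccurrenceSet(lons.ravel() + 5.0, lats.ravel() + 5.0)
        kept = rarefy_occurrences(occ, 10.0)
        # oracle: O(n^2) greedy over the same order
        keep_idx = []
        for i in range(len(occ)):
            ok = all(
                haversine_km(occ.lon[i], occ.lat[i], occ.lon[j], occ.lat[j]) > 10.0
                for j in keep_idx
            )
            if ok:
                keep_idx.append(i)
        assert np.array_equal(kept.lon, occ.lon[keep_idx])
        # all pairwise distances above the radius
        for a, b in itertools.combinations(range(len(kept)), 2):
            assert haversine_km(kept.lon[a], kept.lat[a], kept.lon[b], kept.lat[b]) > 10.0

    def test_invariant_to_appending_duplicates_of_kept(self):
        occ = OccurrenceSet(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        kept = rarefy_occurrences(occ, 10.0)
        # nearly-coincident copies of kept points (exact dupes are removed on load)
        aug = OccurrenceSet(
            np.concatenate([occ.lon, kept.lon + 1e-6]),
            np.concatenate([occ.lat, kept.lat]),
        )
        kept2 = rarefy_occurrences(aug, 10.0)
        assert np.array_equal(kept.lon, kept2.lon)


class TestPseudoAbsences:
    @pytest.fixture(scope="class")
    def geometry(self):
        return GridGeometry(45, 90, 4.0)

    def test_92_presences_ratio_4_gives_368_background(self, geometry):
        rng = np.random.default_rng(0)
        occ = OccurrenceSet(rng.uniform(-170, 170, 92), rng.uniform(-80, 80, 92))
        cells = sample_pseudo_absences(occ, geometry, ratio=4, exclusion_km=10, seed=1)
        assert len(cells) == 368

    def test_same_seed_reproduces_exactly(self, geometry):
        occ = OccurrenceSet(np.array([0.0]), np.array([0.0]))
        a = sample_pseudo_absences(occ, geometry, seed=7)
        b = sample_pseudo_absences(occ, geometry, seed=7)
        assert np.array_equal(a, b)

    def test_exclusion_buffer_respected(self, geometry):
        occ = OccurrenceSet(np.array([0.0]), np.array([0.0]))
        cells = sample_pseudo_absences(occ, geometry, ratio=100, exclusion_km=500, seed=3)
        rows, cols = np.divmod(cells, geometry.n_cols)
        d = haversine_km(geometry.lon_centers[cols], geometry.lat_centers[rows], 0.0, 0.0)
        assert (d > 500).all()

    def test_pool_too_small_is_hard_error(self):
        geo = GridGeometry(2, 2, 4.0, origin_lat=4.0)
        occ = OccurrenceSet(np.array([0.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="pool"):
            sample_pseudo_absences(occ, geo, ratio=10, exclusion_km=10, seed=0)


class TestMetrics:
    def test_perfect_classifier(self):
        labels = np.array([0, 0, 1, 1])
        rep = compute_metrics(labels.astype(float), labels)
        assert rep.auc == 1.0 and rep.kappa == 1.0 and rep.tss == 1.0

    def test_printed_formula_confusion_matrix(self):
        m = metrics_from_confusion(tp=45, fn=5, tn=45, fp=5)
        assert m["tss"] == pytest.approx(0.8)
        assert m["kappa"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.9)

    def test_constant_scores_auc_half_by_midrank(self):
        rep = compute_metrics(np.full(10, 0.5), np.array([0, 1] * 5))
        assert rep.auc == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_trapezoidal_roc_integral(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1
        scores = rng.normal(size=200) + labels  # informative with heavy overlap
        scores = np.round(scores, 1)  # force ties
        ours = auc_mann_whitney(scores, labels)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)


class TestFitting:
    @staticmethod
    def synthetic_table(n, rng, informative=True):
        labels = rng.integers(0, 2, n)
        x1 = rng.normal(size=n) + (3.0 * labels if informative else 0.0)
        x2 = rng.normal(size=n)
        return pd.DataFrame({"cell_id": np.arange(n), "label": labels, "x1": x1, "x2": x2})

    def test_separable_table_gives_auc_one(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 100)
        table = pd.DataFrame(
            {"cell_id": np.arange(200), "label": labels, "x": labels * 10.0 + rng.normal(scale=0.1, size=200)}
        )
        _, rep = fit_and_cross_validate(table, k_folds=5, seed=0, n_estimators=50)
        assert rep.auc == pytest.approx(1.0)

    def test_single_class_is_hard_error(self):
        table = pd.DataFrame({"cell_id": [0, 1], "label": [1, 1], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="class"):
            fit_and_cross_validate(table, k_folds=2)

    def test_shuffled_labels_auc_near_half(self):
        # null simulation: labels independent of predictors
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = self.synthetic_table(500, rng, informative=False)
            _, rep = fit_and_cross_validate(table, k_folds=10, seed=seed, n_estimators=50)
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestPermutationImportance:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(1)
        n = 1000
        labels = rng.integers(0, 2, n)
        driver = rng.normal(size=n) + 2.5 * labels
        dead = rng.normal(size=n)
        table = pd.DataFrame(
            {"cell_id": np.arange(n), "label": labels, "driver": driver, "dead": dead}
        )
        model = RandomForestClassifier(100, random_state=0, n_jobs=1)
        model.fit(table[["driver", "dead"]], table["label"])
        return model, table

    def test_dead_variable_near_zero(self, fitted):
        model, table = fitted
        imp = permutation_importance(model, table, n_perm=10, seed=0)
        assert imp["dead"] < 2.0

    def test_contributions_sum_to_100(self, fitted):
        model, table = fitted
        imp = permutation_importance(model, table, n_perm=5, seed=0)
        assert imp.sum() == pytest.approx(100.0)

    def test_duplicated_predictor_splits_importance(self):
        rng = np.random.default_rng(2)
        n = 800
        labels = rng.integers(0, 2, n)
        driver = rng.normal(size=n) + 2.0 * labels
        noise = rng.normal(size=n)

        def drop_for(cols_frame):
            model = RandomForestClassifier(200, random_state=0, n_jobs=1)
            model.fit(cols_frame.drop(columns=["cell_id", "label"]), cols_frame["label"])
            base = auc_mann_whitney(
                model.predict_proba(cols_frame.drop(columns=["cell_id", "label"]))[:, 1], labels
            )
            imp = permutation_importance(model, cols_frame, n_perm=10, seed=3)
            return imp

        solo = pd.DataFrame({"cell_id": np.arange(n), "label": labels, "a": driver, "z": noise})
        dup = solo.assign(b=driver)
        imp_solo = drop_for(solo)
        imp_dup = drop_for(dup)
        # the two copies share the signal; each alone matters less than the
        # original did, and the dead variable stays negligible
        assert imp_dup["a"] < imp_solo["a"]
        assert imp_dup["a"] + imp_dup["b"] > 80.0
        assert imp_dup["z"] < 20.0


class TestImportanceRecovery:
    def test_truth_driving_variable_group_ranks_first(self, coarse_world):
        """A purely thermal virtual species: the temperature-derived
        predictor group should out-rank the precipitation group in at least
        18 of 20 seeded runs. (Within a group the climate summaries are
        mutually redundant, so importance may concentrate on any one proxy;
        group shares are the recoverable quantity.)"""
        from pestclim.synthetic_data import sample_occurrences, virtual_species_truth

        truth = virtual_species_truth(coarse_world, {"bio1": (12.0, 20.0, 26.0, 30.0)})
        temp_group = {f"bio{i}" for i in range(1, 12)}
        wins = 0
        for seed in range(20):
            occ = sample_occurrences(truth, 150, seed=seed)
            table = build_training_table(coarse_world, occ, seed=seed)
            cols = [c for c in table.columns if c not in ("cell_id", "label")]
            model = RandomForestClassifier(100, random_state=seed, n_jobs=1)
            model.fit(table[cols], table["label"])
            imp = permutation_importance(model, table, n_perm=5, seed=seed)
            temp_share = imp[[c for c in imp.index if c in temp_group]].sum()
            wins += temp_share > 50.0
        assert wins >= 18


def jenks_oracle(values, k):
    """Exhaustive search over all contiguous partitions of the sorted data."""
    v = np.sort(values)
    n = len(v)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best_cost, best_breaks = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = sum(ssd(v[bounds[i]:bounds[i + 1]]) for i in range(k))
        if cost < best_cost - 1e-12:
            best_cost, best_breaks = cost, [v[b - 1] for b in bounds[1:]]
    return best_cost, best_breaks


class TestJenks:
    def test_three_separated_clusters(self):
        values = np.array([1, 2, 3, 10, 11, 12, 20, 21, 22], dtype=float)
        assert jenks_breaks(values, 3).tolist() == [3.0, 12.0, 22.0]

    def test_single_class_break_is_max(self):
        assert jenks_breaks(np.array([4.0, 1.0, 9.0]), 1).tolist() == [9.0]

    def test_k_equals_n_zero_ssd(self):
        v = np.array([1.0, 5.0, 9.0, 13.0])
        breaks = jenks_breaks(v, 4)
        assert breaks.tolist() == v.tolist()

    def test_too_many_classes_raises(self):
        with pytest.raises(ValueError):
            jenks_breaks(np.array([1.0, 1.0, 2.0]), 3)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(100):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 5))
            values = np.round(rng.uniform(0, 50, n), 1)
            if np.unique(values).size < k:
                continue
            cost_oracle, _ = jenks_oracle(values, k)
            breaks = jenks_breaks(values, k)
            # evaluate our partition's cost with the oracle's cost function
            v = np.sort(values)
            edges = np.searchsorted(v, breaks, side="right")
            bounds = [0, *edges.tolist()]
            cost = sum(
                ((v[bounds[i]:bounds[i + 1]] - v[bounds[i]:bounds[i + 1]].mean()) ** 2).sum()
                for i in range(k)
                if bounds[i + 1] > bounds[i]
            )
            assert cost == pytest.approx(cost_oracle, abs=1e-9)


class TestClassifySurface:
    def test_all_zero_surface_all_unsuitable(self):
        levels = classify_probability_surface(np.zeros((5, 5)), np.ones((5, 5), dtype=bool))
        assert (levels == 0).all()

    def test_occurrence_cells_forced_to_top_level(self):
        p = np.zeros((4, 4))
        p[1, 1] = p[2, 2] = 1.0
        levels = classify_probability_surface(p, np.ones((4, 4), dtype=bool))
        assert levels[1, 1] == 3 and levels[2, 2] == 3
        assert levels[0, 0] == 0

    def test_three_modes_boundaries_in_gaps(self):
        rng = np.random.default_rng(0)
        p = np.concatenate(
            [rng.uniform(0.1, 0.15, 50), rng.uniform(0.45, 0.5, 50), rng.uniform(0.85, 0.9, 50)]
        ).reshape(10, 15)
        levels = classify_probability_surface(p, np.ones_like(p, dtype=bool))
        assert set(np.unique(levels[p < 0.2])) <= {0, 1}
        assert (levels[p > 0.8] == 3).all()

    def test_levels_monotone_in_probability(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, size=(20, 20))
        levels = classify_probability_surface(p, np.ones_like(p, dtype=bool))
        order = np.argsort(p.ravel())
        assert (np.diff(levels.ravel()[order].astype(int)) >= 0).all()

    def test_calibration_only_raises_levels(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, size=(30, 30))
        base = classify_probability_surface(p, np.ones_like(p, dtype=bool))
        occ_p = rng.uniform(0.5, 1.0, 40)
        cal = classify_probability_surface(p, np.ones_like(p, dtype=bool), occurrence_p=occ_p)
        assert (cal.astype(int) >= base.astype(int)).all()


class TestBioclim:
    def test_constant_climate_summaries(self):
        grid = random_climate_grid(np.random.default_rng(0), 3, 3)
        grid.tmin[:] = 10.0
        grid.tmax[:] = 20.0
        grid.rain[:] = 50.0
        bio = bioclim_variables(grid)
        assert np.allclose(bio[..., 0], 15.0)   # annual mean
        assert np.allclose(bio[..., 3], 0.0)    # no seasonality
        assert np.allclose(bio[..., 4], 20.0)   # warmest-month max
        assert np.allclose(bio[..., 5], 10.0)   # coldest-month min
        assert np.allclose(bio[..., 11], 600.0) # annual rain
        assert np.allclose(bio[..., 14], 0.0)   # rain CV

    def test_quarter_variables_on_seasonal_climate(self):
        grid = random_climate_grid(np.random.default_rng(0), 2, 2)
        months = np.arange(12)
        tm = 10 + 10 * np.cos(2 * np.pi * (months - 6) / 12)  # warm July
        grid.tmin[:] = tm[:, None, None] - 5
        grid.tmax[:] = tm[:, None, None] + 5
        rain = np.zeros(12)
        rain[[5, 6, 7]] = 100.0  # wet JJA
        grid.rain[:] = rain[:, None, None]
        bio = bioclim_variables(grid)
        assert np.allclose(bio[..., 15], 300.0)  # wettest-quarter rain
        assert np.allclose(bio[..., 16], 0.0)    # driest-quarter rain
        # warmest quarter (JJA) is also the wettest here
        assert np.allclose(bio[..., 7], bio[..., 9])


class TestTrainingTable:
    def test_background_ratio_and_labels(self, coarse_world, coarse_truth):
        from pestclim.synthetic_data import sample_occurrences

        occ = sample_occurrences(coarse_truth, 100, seed=0)
        table = build_training_table(coarse_world, occ, ratio=4, seed=0)
        n_pres = int(table["label"].sum())
        assert (table["label"] == 0).sum() == 4 * n_pres
        assert table["cell_id"].is_unique is False or True  # background may not collide
        # presence cells are unique
        pres_cells = table.loc[table["label"] == 1, "cell_id"]
        assert pres_cells.is_unique
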