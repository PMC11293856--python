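import numpy as np
import pandas as pd
import pytest

import admkit
from admkit.adm import STATE_COABSENCE, STATE_COPRESENCE

FEATURES = ["temperature", "salinity", "nitrate", "silicate"]


def make_grid(rng, n_cells=100, time_label="present"):
    lat = rng.uniform(-60, 60, n_cells)
    lon = rng.uniform(-180, 180, n_cells)
    features = np.column_stack([
        rng.uniform(0, 30, n_cells),
        rng.normal(35, 0.2, n_cells),
        rng.uniform(0, 25, n_cells),
        rng.uniform(0, 30, n_cells),
    ])
    return admkit.GridField(lat, lon, features, list(FEATURES), time_label)


def make_env(rng, n):
    features = np.column_stack([
        rng.uniform(0, 30, n), rng.normal(35, 0.2, n),
        rng.uniform(0, 25, n), rng.uniform(0, 30, n),
    ])
    return admkit.EnvTable([f"s{i}" for i in range(n)], features, list(FEATURES))


class TestMapSamplesToGrid:
    def test_exact_cell_match_returns_cell_values(self, rng):
        grid = make_grid(rng, 50)
        meta = pd.DataFrame(
            {"latitude": [grid.lat[7]], "longitude": [grid.lon[7]], "month": [1]},
            index=["s0"],
        )
        env, rejected = admkit.map_samples_to_grid(meta, grid)
        assert rejected == []
        np.testing.assert_array_equal(env.features[0], grid.features[7])

    def test_neighbourhood_mean_of_two_cells(self):
        grid = admkit.GridField(
            lat=[10.0, 11.0], lon=[20.0, 20.0],
            features=[[10.0, 35, 5, 5], [12.0, 35, 5, 5]],
            feature_names=list(FEATURES),
        )
        meta = pd.DataFrame(
            {"latitude": [10.5], "longitude": [20.2], "month": [1]}, index=["s0"]
        )
        env, _ = admkit.map_samples_to_grid(meta, grid, radius=2.0)
        assert env.features[0, 0] == pytest.approx(11.0)

    def test_matches_brute_force_oracle(self, rng):
        grid = make_grid(rng, 200)
        meta = pd.DataFrame(
            {
                "latitude": rng.uniform(-60, 60, 100),
                "longitude": rng.uniform(-180, 180, 100),
                "month": 1,
            },
            index=[f"s{i}" for i in range(100)],
        )
        env, rejected = admkit.map_samples_to_grid(meta, grid, radius=5.0)
        got = dict(zip(env.sample_ids, env.features))
        for sid, rec in meta.iterrows():
            inside = [
                i for i in range(grid.n_cells)
                if abs(grid.lat[i] - rec.latitude) <= 5.0
                and abs(grid.lon[i] - rec.longitude) <= 5.0
            ]
            if not inside:
                assert sid in rejected
            else:
                expected = grid.features[inside].mean(axis=0)
                np.testing.assert_allclose(got[sid], expected, atol=1e-12)

    def test_unresolvable_sample_reported_not_dropped(self, rng):
        grid = make_grid(rng, 10)
        meta = pd.DataFrame(
            {"latitude": [89.0], "longitude": [0.0], "month": [1]}, index=["far"]
        )
        _, rejected = admkit.map_samples_to_grid(meta, grid, radius=1.0)
        assert rejected == ["far"]


class TestMaskToObservedRange:
    def test_tails_masked_per_percentile_oracle(self, rng):
        env = make_env(rng, 400)
        grid = admkit.GridField(
            lat=rng.uniform(-60, 60, 400), lon=rng.uniform(-180, 180, 400),
            features=env.features.copy(), feature_names=list(FEATURES),
        )
        masked = admkit.mask_to_observed_range(grid, env, 2.5, 97.5)
        lo = np.percentile(env.features, 2.5, axis=0)
        hi = np.percentile(env.features, 97.5, axis=0)
        expected = np.all((grid.features >= lo) & (grid.features <= hi), axis=1)
        np.testing.assert_array_equal(masked.valid_mask, expected)
        assert masked.n_valid < grid.n_cells  # extreme tails excluded

    def test_full_range_keeps_all_finite_cells(self, rng):
        env = make_env(rng, 50)
        grid = make_grid(rng, 80)
        masked = admkit.mask_to_observed_range(grid, env, 0, 100)
        # grid features may exceed env range; q=0/100 keeps the env min..max span
        lo, hi = env.features.min(0), env.features.max(0)
        expected = np.all((grid.features >= lo) & (grid.features <= hi), axis=1)
        np.testing.assert_array_equal(masked.valid_mask, expected)

    def test_out_of_range_feature_empties_mask_with_warning(self, rng):
        env = make_env(rng, 50)
        grid = make_grid(rng, 30)
        grid.features[:, 2] += 1e6  # nitrate far outside everywhere
        with pytest.warns(RuntimeWarning, match="zero valid"):
            masked = admkit.mask_to_observed_range(grid, env)
        assert masked.n_valid == 0

    def test_widening_never_shrinks_valid_set(self, rng):
        env = make_env(rng, 200)
        grid = make_grid(rng, 150)
        narrow = admkit.mask_to_observed_range(grid, env, 10, 90)
        wide = admkit.mask_to_observed_range(grid, env, 2.5, 97.5)
        assert np.all(wide.valid_mask[narrow.valid_mask])


class _ThresholdClassifier:
    """Stub cADM: co-presence iff temperature > 15."""

    def predict(self, X):
        return np.where(X[:, 0] > 15.0, STATE_COPRESENCE, STATE_COABSENCE)


def make_cadm_stub():
    return admkit.AdmModel(
        pair=("a", "b"), variant="cadm", learner="stub", predictors=list(FEATURES),
        estimator=_ThresholdClassifier(), performance={}, training_ranges={},
        seed=0, n_train=10,
    )


class TestProjectCadm:
    def test_copresence_proportion_on_constructed_grid(self, rng):
        grid = make_grid(rng, 200)
        grid.features[:, 0] = np.where(np.arange(200) < 80, 20.0, 10.0)  # 40% warm
        res = admkit.project_cadm(make_cadm_stub(), grid)
        assert res.copresence_proportion == pytest.approx(0.40)

    def test_zero_valid_cells_gives_missing_proportion(self, rng):
        grid = make_grid(rng, 10).with_mask(np.zeros(10, bool))
        res = admkit.project_cadm(make_cadm_stub(), grid)
        assert res.copresence_proportion is None

    def test_projection_is_deterministic(self, rng):
        grid = make_grid(rng, 60)
        a = admkit.project_cadm(make_cadm_stub(), grid)
        b = admkit.project_cadm(make_cadm_stub(), grid)
        np.testing.assert_array_equal(a.states, b.states)

    def test_predictor_mismatch_rejected(self, rng):
        grid = make_grid(rng, 10)
        model = make_cadm_stub()
        model.predictors = ["temperature"]
        with pytest.raises(ValueError, match="predictors"):
            admkit.project_cadm(model, grid)


class TestProjectRadm:
    def _memorizing_radm(self, env, alpha):
        return admkit.fit_radm(
            admkit.AlphaMatrix(("a", "b"), alpha, env.sample_ids), env, "memorize",
            cv_folds=2,
        )

    def test_round_trip_on_training_samples_recovers_rho(self, rng):
        env = make_env(rng, 40)
        alpha = rng.uniform(0, 0.05, 40)
        model = self._memorizing_radm(env, alpha)
        grid = admkit.GridField(
            lat=np.arange(40), lon=np.zeros(40), features=env.features,
            feature_names=list(FEATURES),
        )
        res = admkit.project_radm(model, grid)
        assert abs(res.rho_star_global - (1 - alpha.sum())) < 1e-9

    def test_zero_alpha_star_gives_rho_one(self, rng):
        env = make_env(rng, 20)
        model = self._memorizing_radm(env, np.zeros(20))
        grid = make_grid(rng, 50)
        res = admkit.project_radm(model, grid)
        assert res.rho_star_global == pytest.approx(1.0)

    def test_single_region_covering_all_matches_global(self, rng):
        env = make_env(rng, 30)
        model = self._memorizing_radm(env, rng.uniform(0, 0.1, 30))
        grid = make_grid(rng, 80)
        regions = admkit.assign_regions(grid, {"world": (-90, 90, -180, 180)})
        res = admkit.project_radm(model, grid, regions=regions)
        assert res.rho_star_by_region["world"] == pytest.approx(res.rho_star_global)

    def test_regional_additivity_over_partition(self, rng):
        env = make_env(rng, 30)
        model = self._memorizing_radm(env, rng.uniform(0, 0.1, 30))
        grid = make_grid(rng, 120)
        regions = admkit.assign_regions(
            grid, {"north": (0, 90, -180, 180), "south": (-90, -1e-9, -180, 180)}
        )
        res = admkit.project_radm(model, grid, regions=regions)
        weights = {k: len(v) for k, v in regions.items()}
        total = sum(weights.values())
        weighted = sum(
            weights[k] * (1 - res.rho_star_by_region[k]) for k in regions
        ) / total
        assert weighted == pytest.approx(1 - res.rho_star_global, abs=1e-9)


class TestAssignRegions:
    def test_single_rectangle_covers_everything(self, rng):
        grid = make_grid(rng, 40)
        regions = admkit.assign_regions(grid, {"all": (-90, 90, -180, 180)})
        assert len(regions["all"]) == grid.n_valid

    def test_disjoint_boxes_match_brute_force(self, rng):
        grid = make_grid(rng, 150)
        spec = {"west": (-90, 90, -180, 0 - 1e-9), "east": (-90, 90, 0, 180)}
        regions = admkit.assign_regions(grid, spec)
        for name, (lat0, lat1, lon0, lon1) in spec.items():
            expected = {
                i for i in np.flatnonzero(grid.valid_mask)
                if lat0 <= grid.lat[i] <= lat1 and lon0 <= grid.lon[i] <= lon1
            }
            assert set(regions[name]) == expected

    def test_overlap_rejected(self, rng):
        grid = make_grid(rng, 50)
        with pytest.raises(ValueError, match="overlap"):
            admkit.assign_regions(
                grid, {"a": (-90, 90, -180, 180), "b": (0, 90, -180, 180)}
            )

    def test_zero_area_region_is_empty(self, rng):
        grid = make_grid(rng, 50)
        regions = admkit.assign_regions(grid, {"nowhere": (89.9, 90, 179.0, 179.1)})
        assert len(regions["nowhere"]) == 0
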