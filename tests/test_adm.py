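import numpy as np
import pytest

import admkit
from admkit.adm import (
    STATE_COABSENCE,
    STATE_COPRESENCE,
    STATE_EXCLUSION,
)


def make_env(rng, n, names=("temperature", "salinity", "nitrate", "silicate")):
    features = np.column_stack([
        rng.uniform(0, 30, n),
        rng.normal(35, 0.2, n),
        rng.uniform(0, 25, n),
        rng.uniform(0, 30, n),
    ])[:, : len(names)]
    return admkit.EnvTable([f"s{i}" for i in range(n)], features, list(names))


def states_from_labels(labels, pair=("a", "b")):
    return admkit.CooccurrenceStates(
        pair=pair, states=np.asarray(labels, dtype=object),
        sample_ids=[f"s{i}" for i in range(len(labels))],
    )


class TestDiscretizeStates:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((2.0, 3.0), STATE_COPRESENCE),
            ((0.0, 0.0), STATE_COABSENCE),
            ((0.0, 5.0), STATE_EXCLUSION),
            ((5.0, 0.0), STATE_EXCLUSION),
        ],
    )
    def test_three_states(self, row, expected):
        values = np.array([row, (1.0, 1.0)])
        table = admkit.AbundanceTable(values, ["s0", "s1"], ["a", "b"])
        st = admkit.discretize_states(table, ("a", "b"))
        assert st.states[0] == expected

    def test_unknown_taxon_rejected(self):
        table = admkit.AbundanceTable(np.ones((2, 2)), ["s0", "s1"], ["a", "b"])
        with pytest.raises(KeyError):
            admkit.discretize_states(table, ("a", "zzz"))


class TestFitCadm:
    def test_temperature_threshold_is_learnable(self, rng):
        env = make_env(rng, 120)
        temp = env.features[:, 0]
        labels = np.where(temp > 15, STATE_COPRESENCE, STATE_COABSENCE)
        model = admkit.fit_cadm(states_from_labels(labels), env, "random_forest",
                                seed=0, cv_folds=5, n_estimators=100)
        assert model.performance["cv_value"] >= 0.95

    def test_random_labels_score_near_chance(self, rng):
        env = make_env(rng, 150)
        labels = rng.choice(
            [STATE_COPRESENCE, STATE_COABSENCE, STATE_EXCLUSION], size=150
        )
        model = admkit.fit_cadm(states_from_labels(labels), env, "random_forest",
                                seed=0, cv_folds=5, n_estimators=100)
        assert abs(model.performance["cv_value"] - 1 / 3) < 0.15

    def test_same_seed_reproduces_performance(self, rng):
        env = make_env(rng, 60)
        labels = rng.choice([STATE_COPRESENCE, STATE_EXCLUSION], size=60)
        kwargs = dict(seed=3, cv_folds=4, n_estimators=50)
        a = admkit.fit_cadm(states_from_labels(labels), env, "random_forest", **kwargs)
        b = admkit.fit_cadm(states_from_labels(labels), env, "random_forest", **kwargs)
        assert a.performance == b.performance

    def test_single_state_is_degenerate(self, rng):
        env = make_env(rng, 20)
        with pytest.raises(ValueError, match="degenerate"):
            admkit.fit_cadm(states_from_labels([STATE_COPRESENCE] * 20), env)

    def test_class_probabilities_sum_to_one(self, rng):
        env = make_env(rng, 90)
        labels = rng.choice(
            [STATE_COPRESENCE, STATE_COABSENCE, STATE_EXCLUSION], size=90
        )
        model = admkit.fit_cadm(states_from_labels(labels), env, "random_forest",
                                seed=0, cv_folds=3, n_estimators=50)
        proba = model.predict_proba(env.features)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class TestFitRadm:
    def test_noiseless_smooth_function_of_temperature(self, rng):
        env = make_env(rng, 200)
        temp = env.features[:, 0]
        alpha = admkit.AlphaMatrix(("a", "b"), 0.01 * np.sin(temp / 5) ** 2,
                                   env.sample_ids)
        model = admkit.fit_radm(alpha, env, "random_forest", seed=0, cv_folds=5,
                                n_estimators=200)
        assert model.performance["cv_value"] >= 0.9

    def test_independent_target_has_no_skill(self, rng):
        env = make_env(rng, 150)
        alpha = admkit.AlphaMatrix(("a", "b"), rng.normal(size=150), env.sample_ids)
        model = admkit.fit_radm(alpha, env, "random_forest", seed=0, cv_folds=5,
                                n_estimators=100)
        assert model.performance["cv_value"] <= 0.1

    def test_constant_alpha_warns_but_fits(self, rng):
        env = make_env(rng, 30)
        alpha = admkit.AlphaMatrix(("a", "b"), np.full(30, 0.02), env.sample_ids)
        with pytest.warns(RuntimeWarning, match="constant"):
            model = admkit.fit_radm(alpha, env, "random_forest", n_estimators=20)
        np.testing.assert_allclose(model.predict(env.features), 0.02, atol=1e-12)

    def test_same_seed_reproduces_performance(self, rng):
        env = make_env(rng, 60)
        alpha = admkit.AlphaMatrix(("a", "b"), rng.normal(size=60), env.sample_ids)
        a = admkit.fit_radm(alpha, env, "random_forest", seed=1, n_estimators=50)
        b = admkit.fit_radm(alpha, env, "random_forest", seed=1, n_estimators=50)
        assert a.performance == b.performance


class TestCompareLearners:
    def test_tree_ensembles_beat_linear_svm_on_interactions(self, rng):
        from sklearn.svm import SVR

        env = make_env(rng, 200)
        t, s, n, si = env.features.T
        # interaction-rich, strongly non-linear response
        y = np.sin(t / 3) * (n > n.mean()) + 0.5 * np.cos(si / 4) * (t > t.mean())
        alpha = admkit.AlphaMatrix(("a", "b"), y, env.sample_ids)
        ranking = admkit.compare_learners(
            alpha, env,
            learners=["random_forest", SVR(kernel="linear")],
            seed=0, cv_folds=5, n_estimators=100,
        )
        assert ranking[0].learner == "random_forest"

    def test_single_learner_gives_singleton(self, rng):
        env = make_env(rng, 40)
        alpha = admkit.AlphaMatrix(("a", "b"), rng.normal(size=40), env.sample_ids)
        ranking = admkit.compare_learners(alpha, env, ["random_forest"],
                                          n_estimators=20)
        assert len(ranking) == 1

    def test_duplicate_learners_tie_broken_deterministically(self, rng):
        env = make_env(rng, 40)
        alpha = admkit.AlphaMatrix(("a", "b"), rng.normal(size=40), env.sample_ids)
        r1 = admkit.compare_learners(alpha, env, ["random_forest", "random_forest"],
                                     seed=0, n_estimators=20)
        r2 = admkit.compare_learners(alpha, env, ["random_forest", "random_forest"],
                                     seed=0, n_estimators=20)
        assert [m.learner for m in r1] == [m.learner for m in r2]


class TestPermutationFeatureImportance:
    def test_planted_single_driver_ranks_first(self, rng):
        env = make_env(rng, 150)
        temp = env.features[:, 0]
        alpha = admkit.AlphaMatrix(("a", "b"), (temp / 30) ** 2, env.sample_ids)
        model = admkit.fit_radm(alpha, env, "random_forest", seed=0, n_estimators=100)
        fi = admkit.permutation_feature_importance(model, env, alpha, n_repeats=10, seed=0)
        assert fi.ranked()[0] == "temperature"
        for f in ("salinity", "nitrate", "silicate"):
            assert abs(fi.importances[f]) < 0.1 * fi.importances["temperature"]

    def test_constant_feature_has_zero_importance(self, rng):
        env = make_env(rng, 100)
        env.features[:, 1] = 35.0  # constant salinity: permuting it changes nothing
        temp = env.features[:, 0]
        alpha = admkit.AlphaMatrix(("a", "b"), temp / 30, env.sample_ids)
        model = admkit.fit_radm(alpha, env, "random_forest", seed=0, n_estimators=50)
        fi = admkit.permutation_feature_importance(model, env, alpha, n_repeats=5, seed=0)
        assert fi.importances["salinity"] == 0.0

    def test_fixed_seed_reproduces_vector(self, rng):
        env = make_env(rng, 80)
        alpha = admkit.AlphaMatrix(("a", "b"), rng.normal(size=80), env.sample_ids)
        model = admkit.fit_radm(alpha, env, "random_forest", seed=0, n_estimators=30)
        a = admkit.permutation_feature_importance(model, env, alpha, n_repeats=5, seed=9)
        b = admkit.permutation_feature_importance(model, env, alpha, n_repeats=5, seed=9)
        assert a.importances == b.importances

    def test_agrees_with_sklearn_oracle(self, rng):
        from sklearn.inspection import permutation_importance

        env = make_env(rng, 150)
        temp = env.features[:, 0]
        alpha = admkit.AlphaMatrix(("a", "b"), (temp / 30) ** 2 + 0.05 * rng.normal(size=150),
                                   env.sample_ids)
        model = admkit.fit_radm(alpha, env, "random_forest", seed=0, n_estimators=100)
        ours = admkit.permutation_feature_importance(model, env, alpha,
                                                     n_repeats=30, seed=0)
        ref = permutation_importance(model.estimator, env.features, alpha.alpha,
                                     n_repeats=30, random_state=0, scoring="r2")
        for i, name in enumerate(env.feature_names):
            assert ours.importances[name] == pytest.approx(
                ref.importances_mean[i], abs=0.05
            )

    def test_zero_repeats_rejected(self, rng):
        env = make_env(rng, 30)
        alpha = admkit.AlphaMatrix(("a", "b"), rng.normal(size=30), env.sample_ids)
        model = admkit.fit_radm(alpha, env, "random_forest", seed=0, n_estimators=10)
        with pytest.raises(ValueError):
            admkit.permutation_feature_importance(model, env, alpha, n_repeats=0)
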