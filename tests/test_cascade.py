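import numpy as np
import pandas as pd
import pytest

from cascade_sdm import (
    CascadeClassifier,
    SurveyDataset,
    assemble_cascade,
    cascade_from_json,
    cascade_to_json,
    normalize_environment,
    predict_cascade,
    screen_copredictors,
    train_baseline,
    train_submodel,
)
from cascade_sdm.exceptions import CompositionError, DomainError, SchemaError
from cascade_sdm.simulate import simulate_community

from .conftest import small_sim_config


@pytest.fixture(scope="module")
def survey(quick_config):
    data, _ = simulate_community(small_sim_config(seed=21))
    return normalize_environment(data)


@pytest.fixture(scope="module")
def baseline(survey, quick_config):
    return train_baseline(survey, "target", quick_config, folds=3, seed=5)


@pytest.fixture(scope="module")
def cascade(survey, baseline, quick_config):
    subs = {
        sp: train_submodel(survey, sp, quick_config, folds=3, seed=6 + i)
        for i, sp in enumerate(["strong_co", "weak_co"])
    }
    return assemble_cascade(
        survey, "target", ["strong_co", "weak_co"], subs, quick_config, folds=3, seed=7
    )


class TestBaseline:
    def test_env_driven_species_scores_above_chance(self, baseline):
        assert baseline.cv.median_k > 0.15
        assert baseline.input_species == []
        assert baseline.weights.n_inputs == 6

    def test_species_independent_of_environment_near_chance(self, survey, quick_config):
        base = train_baseline(survey, "noise_sp", quick_config, folds=3, seed=5)
        assert abs(base.cv.median_k) < 0.2

    def test_unnormalized_data_rejected(self, quick_config):
        data, _ = simulate_community(small_sim_config(seed=3))
        with pytest.raises(DomainError, match="normalized"):
            train_baseline(data, "target", quick_config)


@pytest.fixture(scope="module")
def screening(survey, baseline, quick_config):
    return screen_copredictors(
        survey,
        "target",
        baseline,
        ["strong_co", "noise_sp"],
        quick_config,
        folds=3,
        seed=8,
    )


class TestScreening:
    def test_informative_candidate_outscores_noise(self, screening):
        by_name = {c.species: c for c in screening.candidates}
        assert by_name["strong_co"].median_kappa > by_name["noise_sp"].median_kappa
        assert abs(by_name["strong_co"].r) > abs(by_name["noise_sp"].r)

    def test_selection_flag_applies_ci_exceedance_rule(self, screening):
        for c in screening.candidates:
            assert c.selected == (c.median_kappa > screening.baseline.ci_high)

    def test_empty_candidate_list_echoes_baseline(self, survey, baseline, quick_config):
        res = screen_copredictors(survey, "target", baseline, [], quick_config, folds=3, seed=8)
        assert res.candidates == []
        assert res.baseline.k == pytest.approx(baseline.cv.median_k, abs=0.5)

    def test_target_as_its_own_candidate_rejected(self, survey, baseline, quick_config):
        with pytest.raises(DomainError):
            screen_copredictors(survey, "target", baseline, ["target"], quick_config)


class TestSubmodel:
    def test_env_driven_copredictor_materially_above_chance(self, survey, quick_config):
        sub = train_submodel(survey, "strong_co", quick_config, folds=3, seed=11)
        assert sub.cv.median_k > 0.3

    def test_same_seed_gives_identical_weights(self, survey, quick_config):
        a = train_submodel(survey, "strong_co", quick_config, folds=3, seed=12)
        b = train_submodel(survey, "strong_co", quick_config, folds=3, seed=12)
        np.testing.assert_array_equal(
            a.weights.input_to_hidden, b.weights.input_to_hidden
        )

    def test_unknown_species_rejected(self, survey, quick_config):
        with pytest.raises(SchemaError):
            train_submodel(survey, "kraken", quick_config)


class TestAssembleAndPredict:
    def test_target_network_input_count(self, cascade):
        spec = cascade.target_model
        assert spec.weights.n_inputs == 6 + 2
        assert spec.input_mode == {
            "strong_co": "predicted_probability",
            "weak_co": "predicted_probability",
        }

    def test_empty_selection_degenerates_to_baseline_shape(self, survey, quick_config):
        model = assemble_cascade(survey, "target", [], {}, quick_config, folds=3, seed=7)
        assert model.target_model.weights.n_inputs == 6
        assert model.sub_models == {}

    def test_submodel_for_unselected_species_rejected(self, survey, quick_config, cascade):
        with pytest.raises(CompositionError):
            assemble_cascade(
                survey,
                "target",
                ["strong_co"],
                dict(cascade.sub_models),
                quick_config,
                folds=3,
                seed=7,
            )

    def test_missing_submodel_rejected(self, survey, quick_config):
        with pytest.raises(CompositionError):
            assemble_cascade(survey, "target", ["strong_co"], {}, quick_config)

    def test_predictions_identical_without_species_columns(self, cascade, survey):
        p_full, b_full = predict_cascade(cascade, survey)
        env_only = survey.environment.copy()
        p_env, b_env = predict_cascade(cascade, env_only)
        np.testing.assert_array_equal(p_full, p_env)
        np.testing.assert_array_equal(b_full, b_env)

    def test_single_site_row(self, cascade, survey):
        p, b = predict_cascade(cascade, survey.environment.iloc[[0]])
        assert p.shape == (1,) and 0 < p[0] < 1 and b[0] in (0, 1)

    def test_column_order_irrelevant(self, cascade, survey):
        env = survey.environment
        shuffled = env[list(env.columns[::-1])]
        np.testing.assert_array_equal(
            predict_cascade(cascade, env)[0], predict_cascade(cascade, shuffled)[0]
        )

    def test_missing_environment_column_named(self, cascade, survey):
        with pytest.raises(SchemaError, match="e3"):
            predict_cascade(cascade, survey.environment.drop(columns=["e3"]))

    def test_json_round_trip_preserves_predictions(self, cascade, survey):
        back = cascade_from_json(cascade_to_json(cascade))
        np.testing.assert_array_equal(
            predict_cascade(cascade, survey)[0], predict_cascade(back, survey)[0]
        )


class TestCascadeClassifier:
    def test_retrain_and_reuse_agree_with_perfect_submodels(self, survey):
        """With sub-models that output the observed occurrences exactly, the
        retrained target network sees the same training matrix as the reuse
        (step-2) network, so the two compositions coincide."""
        X = survey.env_matrix()
        y = survey.species_vector("target")
        C = survey.occurrence[["strong_co"]].to_numpy(dtype=float)
        stub = [lambda M, col=C[:, 0]: col if len(M) == len(col) else None]

        kw = dict(n_hidden=3, max_iter=150, tol=1e-6, restarts=2, random_state=9)
        a = CascadeClassifier(composition="retrain", oof="in_sample", **kw)
        a.fit(X, y, copredictors=C, submodels=stub)
        b = CascadeClassifier(composition="reuse", **kw)
        b.fit(X, y, copredictors=C, submodels=stub)
        np.testing.assert_array_equal(
            a.target_net_.network_.input_to_hidden, b.target_net_.network_.input_to_hidden
        )
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = CascadeClassifier(n_hidden=4, composition="reuse")
        assert clone(est).get_params()["composition"] == "reuse"

    def test_no_copredictors_equals_plain_network(self, survey):
        from cascade_sdm import SigmoidNetClassifier

        X = survey.env_matrix()
        y = survey.species_vector("target")
        kw = dict(n_hidden=3, max_iter=150, tol=1e-6, restarts=2, random_state=2)
        casc = CascadeClassifier(**kw).fit(X, y)
        # the degenerate cascade is a single env-only network
        assert casc.n_copredictors_ == 0
        assert casc.predict_proba(X).shape == (len(y), 2)
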