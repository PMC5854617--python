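import numpy as np
import pytest
import sklearn.metrics
import statsmodels.stats.inter_rater as smir
from hypothesis import given, settings
from hypothesis import strategies as st

from cascade_sdm import (
    ConfusionMatrix,
    binarize,
    cohen_kappa,
    confusion,
    cross_validate,
    kappa_ci,
    landis_koch,
    roc_analysis,
)
from cascade_sdm.exceptions import DegenerateError, DomainError

from .oracles import exhaustive_youden_cutoff

matrices = st.tuples(
    st.integers(0, 100), st.integers(0, 100), st.integers(0, 100), st.integers(0, 100)
).filter(lambda t: sum(t) > 0)


def _matrix_to_vectors(m: ConfusionMatrix):
    pred = np.array([1] * (m.tp + m.fp) + [0] * (m.fn + m.tn))
    obs = np.array([1] * m.tp + [0] * m.fp + [1] * m.fn + [0] * m.tn)
    return pred, obs


class TestBinarizeAndConfusion:
    def test_threshold_rule(self):
        np.testing.assert_array_equal(binarize([0.3, 0.6], 0.5), [0, 1])

    def test_score_equal_to_cutoff_counts_as_presence(self):
        assert binarize([0.5], 0.5)[0] == 1

    def test_zero_cutoff_gives_all_ones(self):
        assert binarize([0.0, 0.2, 1.0], 0.0).tolist() == [1, 1, 1]

    def test_confusion_tallies_outcomes(self):
        m = confusion([1, 0], [1, 0])
        assert (m.tp, m.tn, m.fp, m.fn) == (1, 1, 0, 0)
        m2 = confusion([1, 1], [0, 0])
        assert m2.fp == 2

    def test_empty_vectors_rejected(self):
        with pytest.raises(DomainError):
            confusion([], [])


class TestCohenKappa:
    def test_published_confusion_matrix_value(self):
        # 36 true absences, 0 missed presences, 4 false presences, 13 hits
        res = cohen_kappa(ConfusionMatrix(tp=13, fp=4, fn=0, tn=36))
        assert round(res.k, 3) == 0.815

    def test_near_perfect_matrix_by_direct_arithmetic(self):
        # exact rational value of the chance-corrected formula: 856/1121
        res = cohen_kappa(ConfusionMatrix(tp=12, fp=4, fn=1, tn=36))
        assert res.k == pytest.approx(856 / 1121, abs=1e-12)

    def test_perfect_agreement_is_one(self):
        assert cohen_kappa(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10)).k == 1.0

    def test_constant_prediction_at_half_prevalence_is_chance(self):
        assert cohen_kappa(ConfusionMatrix(tp=5, fp=5, fn=0, tn=0)).k == 0.0

    def test_single_class_everything_rejected(self):
        with pytest.raises(DegenerateError):
            cohen_kappa(ConfusionMatrix(tp=10, fp=0, fn=0, tn=0))

    @given(matrices)
    @settings(max_examples=200, deadline=None)
    def test_equals_po_pe_form_and_sklearn(self, cells):
        tp, fp, fn, tn = cells
        m = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        n = m.n
        po = (tp + tn) / n
        pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
        if pe == 1.0:
            return
        k = cohen_kappa(m).k
        assert k == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        pred, obs = _matrix_to_vectors(m)
        if len(set(pred)) > 1 or len(set(obs)) > 1:
            assert k == pytest.approx(
                sklearn.metrics.cohen_kappa_score(pred, obs), abs=1e-12
            )

    @given(matrices)
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_simultaneous_label_swap(self, cells):
        tp, fp, fn, tn = cells
        try:
            a = cohen_kappa(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)).k
            b = cohen_kappa(ConfusionMatrix(tp=tn, fp=fn, fn=fp, tn=tp)).k
        except DegenerateError:
            return
        assert a == pytest.approx(b, abs=1e-12)


class TestKappaCI:
    def test_perfect_matrix_interval_collapses(self):
        low, high = kappa_ci(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10))
        assert (low, high) == (1.0, 1.0)

    @given(matrices)
    @settings(max_examples=100, deadline=None)
    def test_interval_brackets_kappa(self, cells):
        tp, fp, fn, tn = cells
        m = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        try:
            res = cohen_kappa(m)
        except DegenerateError:
            return
        assert res.ci_low <= res.k <= res.ci_high

    def test_quadrupled_counts_halve_the_width(self):
        m = ConfusionMatrix(tp=13, fp=4, fn=2, tn=36)
        w1 = np.diff(kappa_ci(m))[0]
        w4 = np.diff(kappa_ci(m.scaled(4)))[0]
        assert w4 == pytest.approx(w1 / 2, rel=1e-6)

    def test_matches_statsmodels_standard_error(self):
        for cells in [(13, 4, 2, 36), (20, 10, 5, 30), (8, 3, 9, 40)]:
            tp, fp, fn, tn = cells
            m = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
            table = np.array([[tn, fn], [fp, tp]], dtype=float)
            ref = smir.cohens_kappa(table, return_results=True)
            low, high = kappa_ci(m)
            assert cohen_kappa(m).k == pytest.approx(ref.kappa, abs=1e-12)
            assert (high - low) / 2 == pytest.approx(1.959963985 * ref.std_kappa, rel=1e-6)


class TestLandisKoch:
    @pytest.mark.parametrize(
        "k,label",
        [
            (-0.2, "poor"),
            (0.0, "poor"),
            (0.1, "slight"),
            (0.35, "fair"),
            (0.55, "moderate"),
            (0.627, "substantial"),
            (0.8, "substantial"),
            (0.815, "almost_perfect"),
            (1.0, "almost_perfect"),
        ],
    )
    def test_bands(self, k, label):
        assert landis_koch(k) == label

    def test_field_aliases_for_top_bands(self):
        assert landis_koch(0.627, alias=True) == "good"
        assert landis_koch(0.815, alias=True) == "very good"

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            landis_koch(1.2)


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.best_cutoff == pytest.approx(0.5)

    def test_identical_scores_uninformative(self):
        r = roc_analysis([0.4] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5)
        assert r.best_cutoff == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateError):
            roc_analysis([0.1, 0.9], [1, 1])

    def test_curve_monotonicity(self):
        rng = np.random.default_rng(8)
        scores = rng.random(100)
        obs = (rng.random(100) < 0.4).astype(int)
        r = roc_analysis(scores, obs)
        assert (np.diff(r.sensitivities) <= 1e-12).all()
        assert (np.diff(r.specificities) >= -1e-12).all()

    def test_auc_equals_mann_whitney_formulation(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            obs = (rng.random(80) < 0.5).astype(int)
            scores = np.clip(obs * 0.2 + rng.random(80) * 0.8, 0, 1)
            if obs.min() == obs.max():
                continue
            r = roc_analysis(scores, obs)
            ref = sklearn.metrics.roc_auc_score(obs, scores)
            assert r.auc == pytest.approx(ref, abs=1e-10)

    def test_best_cutoff_matches_exhaustive_search(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            obs = (rng.random(200) < 0.35).astype(int)
            scores = np.clip(0.4 * obs + rng.random(200) * 0.7, 0, 1)
            if obs.min() == obs.max():
                continue
            r = roc_analysis(scores, obs)
            best_cut, best_j = exhaustive_youden_cutoff(scores, obs)
            pos, neg = obs == 1, obs == 0
            mine_j = (scores[pos] >= r.best_cutoff).mean() + (
                scores[neg] < r.best_cutoff
            ).mean() - 1
            assert mine_j == pytest.approx(best_j, abs=1e-12)
            assert r.best_cutoff == pytest.approx(best_cut, abs=1e-12)


class _PerfectModel:
    def __init__(self, target):
        self.target = target

    def predict_scores(self, data):
        return data.species_vector(self.target).astype(float)


class _ConstantModel:
    def predict_scores(self, data):
        return np.full(data.n_sites, 0.5)


class TestCrossValidate:
    def test_perfect_classifier_stub_gives_unit_kappa(self, small_survey):
        report = cross_validate(
            small_survey, "target", lambda d, s: _PerfectModel("target"), folds=5, seed=0
        )
        assert report.median_k == 1.0
        assert all(f.kappa.k == 1.0 for f in report.folds)

    def test_constant_stub_handled_as_chance_level(self, small_survey):
        report = cross_validate(
            small_survey, "target", lambda d, s: _ConstantModel(), folds=5, seed=0
        )
        assert report.median_k == pytest.approx(0.0, abs=1e-12)

    def test_seeded_run_is_identical(self, small_survey, quick_config):
        from cascade_sdm.cascade import environment_model_factory

        a = cross_validate(
            small_survey, "target", environment_model_factory("target", quick_config),
            folds=3, seed=4,
        )
        b = cross_validate(
            small_survey, "target", environment_model_factory("target", quick_config),
            folds=3, seed=4,
        )
        assert a.to_frame().equals(b.to_frame())

    def test_median_fold_matrix_matches_median_kappa(self, small_survey):
        report = cross_validate(
            small_survey, "target", lambda d, s: _PerfectModel("target"), folds=5, seed=1
        )
        ks = [f.kappa.k for f in report.folds]
        assert cohen_kappa(report.median_fold_matrix).k == pytest.approx(
            min(ks, key=lambda k: abs(k - report.median_k))
        )
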