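import numpy as np
import pandas as pd
import pytest

from wavesweep import (
    WaveletBasisSpec,
    call_class,
    coefficient_functions,
    fit_classifier,
    fit_standardization,
    load_model,
    predict_proba,
    reliability_curve,
    save_model,
    standardize,
)
from wavesweep.funreg_classify import ClassifierModel, _softmax, build_coefficient_vector
from wavesweep.sumstats import N_STATS, FeatureCurves


def _zero_model(classes, p=16, alpha=None):
    spec = WaveletBasisSpec(family="haar", vanishing_moments=1, p=p, j0=0)
    D = N_STATS * p
    sp_train = [
        FeatureCurves(obs_id=str(i), curves=np.full((N_STATS, p), float(i)))
        for i in range(3)
    ]
    return ClassifierModel(
        classes=classes,
        alpha=np.zeros(len(classes)) if alpha is None else np.asarray(alpha),
        Z=np.zeros((D, len(classes))),
        gamma=0.0,
        lam=1.0,
        basis=spec,
        standardization=fit_standardization(sp_train),
    )


class TestPredictProba:
    def test_zero_model_is_uniform(self):
        model = _zero_model(["a", "b", "c"])
        fc = FeatureCurves(obs_id="x", curves=np.random.default_rng(0).normal(size=(N_STATS, 16)))
        probs = predict_proba(model, fc)
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-12)

    def test_intercept_only_closed_form(self):
        model = _zero_model(["a", "b"], alpha=[np.log(2), 0.0])
        fc = FeatureCurves(obs_id="x", curves=np.ones((N_STATS, 16)))
        probs = predict_proba(model, fc)
        np.testing.assert_allclose(probs, [2 / 3, 1 / 3], atol=1e-12)

    def test_probabilities_sum_to_one(self, trained_classifier, separable_test):
        feats, _ = separable_test
        for fc in feats[:10]:
            assert predict_proba(trained_classifier, fc).sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_softmax_shift_invariance(self):
        eta = np.array([0.3, -1.2, 2.0])
        np.testing.assert_allclose(_softmax(eta), _softmax(eta + 17.5), atol=1e-12)

    def test_dimension_mismatch_rejected(self, trained_classifier):
        fc = FeatureCurves(obs_id="bad", curves=np.ones((N_STATS, 32)))
        with pytest.raises(ValueError):
            predict_proba(trained_classifier, fc)


class TestCallClass:
    CLASSES = ["neutral", "sweep"]

    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((0.25, 0.75), "sweep"),
            ((0.31, 0.69), "neutral"),  # at/below 0.7 demoted to neutral
            ((0.30, 0.70), "neutral"),
            ((0.5, 0.5), "neutral"),  # tie rule
        ],
    )
    def test_threshold_rule(self, probs, expected):
        assert call_class(np.array(probs), self.CLASSES) == expected

    def test_three_class_demotion(self):
        classes = ["adaptive_introgression", "neutral", "sweep"]
        probs = np.array([0.65, 0.30, 0.05])
        assert call_class(probs, classes) == "neutral"
        assert call_class(np.array([0.75, 0.2, 0.05]), classes) == (
            "adaptive_introgression"
        )


class TestFitClassifier:
    def test_separable_classes_high_heldout_accuracy(
        self, trained_classifier, separable_test
    ):
        feats, labels = separable_test
        correct = sum(
            trained_classifier.classes[int(np.argmax(predict_proba(trained_classifier, fc)))] == lab
            for fc, lab in zip(feats, labels)
        )
        assert trained_classifier.cv_report.cv_accuracy.max() >= 0.99
        assert correct / len(labels) >= 0.95

    def test_permuted_labels_at_chance(self, separable_train):
        # permutation null: the cross-validated held-out accuracy on the
        # permuted dataset is chance.  (Accuracy against the TRUE labels
        # is not a valid null here: on separable features the fit
        # amplifies the permutation's chance overlap with the truth into
        # a systematically right-or-wrong rule.)
        feats, labels = separable_train
        rng = np.random.default_rng(42)
        permuted = list(rng.permutation(labels))
        model = fit_classifier(
            feats, permuted, gamma_grid=(0.0,), level_grid=(0,),
            folds=5, seed=3, n_lambda=6,
        )
        cv_acc = float(model.cv_report.cv_accuracy.iloc[0])
        se = np.sqrt(0.25 / len(labels))
        assert abs(cv_acc - 0.5) <= 3 * se

    def test_singleton_grid_reported_verbatim(self, separable_train):
        feats, labels = separable_train
        model = fit_classifier(
            feats, labels, gamma_grid=(1.0,), level_grid=(0,),
            folds=5, seed=0, n_lambda=4,
        )
        assert model.gamma == 1.0
        assert model.basis.j0 == 0

    def test_class_smaller_than_folds_rejected(self, separable_train):
        feats, labels = separable_train
        small = [*range(6), *range(30, 36)]  # six observations per class
        with pytest.raises(ValueError, match="stratified"):
            fit_classifier([feats[i] for i in small],
                           [labels[i] for i in small], folds=10,
                           gamma_grid=(0.0,), level_grid=(0,))

    def test_seeded_fit_is_reproducible(self, separable_train):
        feats, labels = separable_train
        kw = dict(gamma_grid=(0.0,), level_grid=(0, 2), folds=5, seed=7,
                  n_lambda=4)
        a = fit_classifier(feats, labels, **kw)
        b = fit_classifier(feats, labels, **kw)
        assert a.gamma == b.gamma and a.basis.j0 == b.basis.j0
        np.testing.assert_array_equal(a.Z, b.Z)
        np.testing.assert_array_equal(a.alpha, b.alpha)

    def test_huge_lambda_degenerates_to_class_proportions(self, separable_train):
        feats, labels = separable_train
        # unbalance the training set 2:1
        keep = [i for i, lab in enumerate(labels) if lab == "sweep" or i < 15]
        feats = [feats[i] for i in keep]
        labels = [labels[i] for i in keep]
        from wavesweep.funreg_classify import _design_matrix, _fit_multinomial
        from wavesweep.sumstats import fit_standardization

        sp = fit_standardization(feats)
        spec = WaveletBasisSpec(family="haar", vanishing_moments=1, p=16, j0=0)
        X = _design_matrix(feats, sp, spec)
        clf = _fit_multinomial(X, np.asarray(labels), gamma=0.0, lam=1e6)
        probs = clf.predict_proba(X)
        prop = np.mean(np.asarray(labels) == clf.classes_[1])
        np.testing.assert_allclose(probs[:, 1], prop, atol=1e-3)


class TestRidgeEquivalence:
    def test_wavelet_ridge_matches_raw_ridge(self, separable_train, separable_test):
        """gamma=0 fits are invariant to the orthonormal wavelet rotation."""
        from sklearn.linear_model import LogisticRegression

        feats, labels = separable_train
        model = fit_classifier(
            feats, labels, gamma_grid=(0.0,), level_grid=(2,),
            folds=5, seed=5, n_lambda=4,
        )
        sp = model.standardization
        X_raw = np.stack([standardize(fc, sp).curves.ravel() for fc in feats])
        n = len(labels)
        oracle = LogisticRegression(
            l1_ratio=0.0, C=1.0 / (2.0 * n * model.lam),
            solver="lbfgs", max_iter=5000, tol=1e-10,
        ).fit(X_raw, labels)
        test_feats, _ = separable_test
        for fc in test_feats[:20]:
            ours = predict_proba(model, fc)
            raw = oracle.predict_proba(
                standardize(fc, sp).curves.ravel()[None, :]
            )[0]
            np.testing.assert_allclose(ours, raw, atol=1e-4)


class TestCoefficientFunctions:
    def test_zero_model_gives_zero_functions(self):
        model = _zero_model(["a", "b"])
        cf = coefficient_functions(model)
        for label in cf.classes:
            for stat, curve in cf.beta[label].items():
                np.testing.assert_allclose(curve, 0.0)

    def test_block_structure_respected(self):
        model = _zero_model(["a", "b"])
        p = model.basis.p
        model.Z[2 * p : 3 * p, 1] = 1.0  # only the H12 segment of class b
        cf = coefficient_functions(model)
        assert np.allclose(cf.beta["a"]["H12"], 0.0)
        assert not np.allclose(cf.beta["b"]["H12"], 0.0)
        assert np.allclose(cf.beta["b"]["pi"], 0.0)

    def test_lasso_sparser_than_ridge(self, separable_train):
        feats, labels = separable_train
        lasso = fit_classifier(feats, labels, gamma_grid=(1.0,),
                               level_grid=(0,), folds=5, seed=1, n_lambda=6)
        ridge = fit_classifier(feats, labels, gamma_grid=(0.0,),
                               level_grid=(0,), folds=5, seed=1, n_lambda=6)
        n_zero_lasso = int(np.sum(np.abs(lasso.Z) < 1e-10))
        n_zero_ridge = int(np.sum(np.abs(ridge.Z) < 1e-10))
        assert n_zero_lasso >= n_zero_ridge
        assert n_zero_lasso > 0


class TestReliabilityCurve:
    def test_extreme_confident_predictions(self):
        model = _zero_model(["neutral", "sweep"], alpha=[-30.0, 30.0])
        feats = [
            FeatureCurves(obs_id=str(i), curves=np.ones((N_STATS, 16)))
            for i in range(5)
        ]
        table = reliability_curve(model, feats, ["sweep"] * 5)
        assert table.mean_predicted.iloc[-1] == pytest.approx(1.0)
        assert table.observed_fraction.iloc[-1] == pytest.approx(1.0)
        low = _zero_model(["neutral", "sweep"], alpha=[30.0, -30.0])
        table = reliability_curve(low, feats, ["neutral"] * 5)
        assert table.mean_predicted.iloc[0] == pytest.approx(0.0)
        assert table.observed_fraction.iloc[0] == pytest.approx(0.0)

    def test_calibrated_model_tracks_diagonal(self, trained_classifier,
                                              separable_test):
        feats, labels = separable_test
        table = reliability_curve(trained_classifier, feats, labels)
        # well-separated classes: confident windows must be near-correct
        confident = table[table.mean_predicted > 0.9]
        assert (confident.observed_fraction > 0.8).all()

    def test_empty_test_set_rejected(self, trained_classifier):
        with pytest.raises(ValueError):
            reliability_curve(trained_classifier, [], [])


class TestSerialization:
    def test_model_json_round_trip_preserves_predictions(
        self, trained_classifier, separable_test, tmp_path
    ):
        path = tmp_path / "clf.json"
        save_model(trained_classifier, str(path))
        back = load_model(str(path))
        feats, _ = separable_test
        for fc in feats[:5]:
            np.testing.assert_allclose(
                predict_proba(back, fc), predict_proba(trained_classifier, fc),
                atol=1e-12,
            )
        assert back.classes == trained_classifier.classes
        assert back.basis == trained_classifier.basis
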