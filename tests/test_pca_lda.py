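"""PCA subspace, Fisher discriminant, LOOCV protocol, and confusion metrics."""

import numpy as np
import pytest

from fcmotif import (
    ADHD,
    CONTROL,
    FeatureVector,
    compute_metrics,
    fit_lda,
    fit_pca,
    loocv_detection_rate,
    predict_label,
    train_classifier,
)
from fcmotif.pca_lda import loocv_predictions, loocv_predictions_gram


def make_features(X, labels):
    return [FeatureVector(values=x, label=lab) for x, lab in zip(X, labels)]


def gaussian_cohort(rng, n_per_class=40, d=500, separation=6.0):
    """Two well-separated Gaussian clouds in d dimensions."""
    shift = np.zeros(d)
    shift[: d // 5] = separation / np.sqrt(d // 5)
    Xa = rng.standard_normal((n_per_class, d)) + shift
    Xc = rng.standard_normal((n_per_class, d))
    X = np.vstack([Xa, Xc])
    labels = np.array([ADHD] * n_per_class + [CONTROL] * n_per_class)
    return X, labels


class TestFitPca:
    def test_collinear_points_need_one_component(self):
        t = np.arange(5.0)
        X = np.outer(t, [1.0, 2.0, -1.0])
        _, components, fractions = fit_pca(X, 1)
        assert fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert components.shape == (1, 3)

    def test_components_orthonormal(self, rng):
        X = rng.standard_normal((20, 30))
        _, components, _ = fit_pca(X, 10)
        assert np.allclose(components @ components.T, np.eye(10), atol=1e-8)

    def test_full_rank_fractions_sum_to_one(self, rng):
        X = rng.standard_normal((10, 6))
        _, _, fractions = fit_pca(X, 6)
        assert fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(fractions) <= 1e-12)  # non-increasing

    def test_k_capped_at_n_minus_one(self, rng):
        X = rng.standard_normal((5, 50))
        _, components, _ = fit_pca(X, 40)
        assert components.shape[0] == 4

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.standard_normal((25, 40))
        mean, components, fractions = fit_pca(X, 5)
        ref = sklearn.PCA(n_components=5).fit(X)
        assert np.allclose(mean, ref.mean_)
        assert np.allclose(np.abs(np.sum(components * ref.components_, axis=1)), 1.0, atol=1e-8)
        assert np.allclose(fractions, ref.explained_variance_ratio_, atol=1e-10)

    def test_rejects_bad_k(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((5, 5)), 0)


class TestFitLda:
    def test_one_dimensional_closed_form(self):
        Z = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([CONTROL, CONTROL, ADHD, ADHD])
        w, midpoint, scatter = fit_lda(Z, labels)
        assert midpoint == pytest.approx(5.5)
        scores = (Z @ w).ravel()
        assert all(s > midpoint for s, lab in zip(scores, labels) if lab == ADHD)
        assert all(s <= midpoint for s, lab in zip(scores, labels) if lab == CONTROL)

    def test_isotropic_scatter_aligns_with_mean_difference(self):
        # each class is {+-e1, +-e2, +-e3}: within-class scatter exactly 2*I
        base = np.vstack([np.eye(3), -np.eye(3)])
        diff = np.array([3.0, -1.0, 2.0])
        Z = np.vstack([base + diff, base])
        labels = np.array([ADHD] * 6 + [CONTROL] * 6)
        w, _, _ = fit_lda(Z, labels)
        assert np.allclose(np.abs(w @ (diff / np.linalg.norm(diff))), 1.0, atol=1e-12)

    def test_singular_scatter_survives_via_ridge(self):
        Z = np.array([[0.0, 0.0], [1.0, 1.0], [10.0, 10.0], [11.0, 11.0]])  # duplicated feature
        labels = np.array([CONTROL, CONTROL, ADHD, ADHD])
        w, midpoint, _ = fit_lda(Z, labels)
        assert np.all(np.isfinite(w)) and np.isfinite(midpoint)

    def test_generalized_eigenproblem_residual(self, rng):
        """S_B w is proportional to S_W w for the Fisher direction."""
        Z = np.vstack(
            [rng.standard_normal((30, 4)) + [2, 0, 0, 0], rng.standard_normal((30, 4))]
        )
        labels = np.array([ADHD] * 30 + [CONTROL] * 30)
        w, _, scatter = fit_lda(Z, labels)
        lhs = scatter.S_B @ w
        rhs = scatter.S_W @ w
        lam = (w @ lhs) / (w @ rhs)
        assert np.allclose(lhs, lam * rhs, atol=1e-6 * np.abs(lhs).max())

    def test_matches_sklearn_direction(self, rng):
        lda_mod = pytest.importorskip("sklearn.discriminant_analysis")
        Z = np.vstack(
            [rng.standard_normal((40, 5)) + [1.5, -1, 0, 0, 0], rng.standard_normal((40, 5))]
        )
        labels = np.array([ADHD] * 40 + [CONTROL] * 40)
        w, _, _ = fit_lda(Z, labels)
        ref = lda_mod.LinearDiscriminantAnalysis(solver="eigen").fit(
            Z, (labels == ADHD).astype(int)
        )
        ref_w = ref.coef_.ravel() / np.linalg.norm(ref.coef_)
        assert np.allclose(np.abs(w @ ref_w), 1.0, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((4, 2)), np.array([ADHD] * 4))


class TestTrainPredict:
    def test_separable_clouds_reach_perfect_training_accuracy(self, rng):
        X, labels = gaussian_cohort(rng)
        model = train_classifier(make_features(X, labels), k=40)
        preds = [predict_label(model, x) for x in X]
        assert preds == list(labels)

    def test_class_mean_classified_as_adhd(self, rng):
        X, labels = gaussian_cohort(rng)
        model = train_classifier(make_features(X, labels), k=10)
        assert predict_label(model, X[labels == ADHD].mean(axis=0)) == ADHD

    def test_midpoint_tie_goes_to_control(self):
        # hand-built model with exact float arithmetic: score(x) == midpoint
        from fcmotif.pca_lda import PcaLdaModel

        model = PcaLdaModel(
            training_mean=np.zeros(3),
            components=np.array([[1.0, 0.0, 0.0]]),
            explained_variance_fractions=np.array([1.0]),
            k=1,
            w=np.array([1.0]),
            class_means_projected=(4.0, 0.0),
            class_counts=(2, 2),
            class_mean_vectors=np.array([[4.0], [0.0]]),
            decision_midpoint=2.0,
        )
        assert predict_label(model, np.array([2.0, 5.0, -1.0])) == CONTROL  # exactly at midpoint
        assert predict_label(model, np.array([2.5, 0.0, 0.0])) == ADHD

    def test_layout_mismatch_rejected(self, rng):
        X, labels = gaussian_cohort(rng, n_per_class=5, d=20)
        fvs = make_features(X, labels)
        for fv in fvs:
            fv.layout = "A"
        model = train_classifier(fvs, k=3)
        probe = FeatureVector(values=X[0], label=ADHD, layout="B")
        with pytest.raises(ValueError):
            predict_label(model, probe)

    def test_affine_shift_leaves_predictions_unchanged(self, rng):
        X, labels = gaussian_cohort(rng, n_per_class=15, d=60, separation=2.0)
        shift = rng.standard_normal(60) * 5
        m0 = train_classifier(make_features(X, labels), k=10)
        m1 = train_classifier(make_features(X + shift, labels), k=10)
        p0 = [predict_label(m0, x) for x in X]
        p1 = [predict_label(m1, x + shift) for x in X]
        assert p0 == p1


class TestLoocv:
    def test_runs_exactly_n_folds(self, rng):
        X, labels = gaussian_cohort(rng, n_per_class=22, d=30)  # 44 subjects
        preds = loocv_predictions(make_features(X, labels), k=10)
        assert len(preds) == 44

    def test_no_leakage_of_held_out_subject(self, rng):
        """Fold i's model never sees subject i: its prediction must equal that of
        a classifier trained on the other n-1 subjects, for any value of x_i."""
        X, labels = gaussian_cohort(rng, n_per_class=6, d=15, separation=3.0)
        fvs = make_features(X, labels)
        model_without_0 = train_classifier(fvs[1:], k=4)
        for scale in (1.0, -5.0, 100.0):
            X2 = X.copy()
            X2[0] = scale * rng.standard_normal(15)
            fold0_pred = loocv_predictions(make_features(X2, labels), k=4)[0]
            assert fold0_pred == predict_label(model_without_0, X2[0])

    def test_separable_cohort_scores_near_100(self, rng):
        X, labels = gaussian_cohort(rng, separation=8.0)
        assert loocv_detection_rate(make_features(X, labels), k=40) >= 95.0

    def test_pure_noise_is_chance_level(self, rng):
        X = rng.standard_normal((200, 500))
        labels = np.array([ADHD, CONTROL] * 100)
        rate = loocv_detection_rate(make_features(X, labels), k=40)
        assert 40.0 <= rate <= 60.0

    def test_gram_scorer_identical_to_canonical(self, rng):
        for sep in (0.0, 1.0, 4.0):
            X, labels = gaussian_cohort(rng, n_per_class=12, d=200, separation=sep)
            fvs = make_features(X, labels)
            assert loocv_predictions(fvs, k=8) == list(loocv_predictions_gram(X, labels, 8))


class TestMetrics:
    def test_kki_style_all_control_prediction(self):
        truth = [CONTROL] * 8 + [ADHD] * 3
        m = compute_metrics([CONTROL] * 11, truth)
        assert m.detection_rate == pytest.approx(72.72, abs=0.01)
        assert m.specificity == 1.0
        assert m.sensitivity == 0.0

    def test_all_adhd_prediction_is_the_complement(self):
        truth = [CONTROL] * 8 + [ADHD] * 3
        m = compute_metrics([ADHD] * 11, truth)
        assert m.detection_rate == pytest.approx(27.27, abs=0.01)
        assert m.specificity == 0.0
        assert m.sensitivity == 1.0

    def test_perfect_prediction(self):
        truth = [ADHD, CONTROL, ADHD]
        m = compute_metrics(truth, truth)
        assert (m.detection_rate, m.specificity, m.sensitivity) == (100.0, 1.0, 1.0)

    def test_identities_hold_on_random_confusions(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            truth = list(rng.choice([ADHD, CONTROL], size=n))
            pred = list(rng.choice([ADHD, CONTROL], size=n))
            m = compute_metrics(pred, truth)
            assert m.TP + m.TN + m.FP + m.FN == n
            assert m.detection_rate == pytest.approx(100.0 * (m.TP + m.TN) / n)
            if m.TP + m.FN:
                assert m.sensitivity == pytest.approx(m.TP / (m.TP + m.FN))
            else:
                assert np.isnan(m.sensitivity)
            if m.TN + m.FP:
                assert m.specificity == pytest.approx(m.TN / (m.TN + m.FP))
            else:
                assert np.isnan(m.specificity)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])
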