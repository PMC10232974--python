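import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from fcsubnet.classifier import (
    FitError,
    classify,
    cross_validate,
    evaluate,
    fit_score_model,
    mann_whitney_auc,
    ppv_npv,
    roc_points,
    score_subjects,
)


class TestScoreModel:
    def test_hand_moments(self):
        P = np.array([[9.0], [11.0], [5.0], [7.0]])
        labels = np.array(["HC", "HC", "SZ", "SZ"])
        m = fit_score_model(P, labels)
        assert m.mu_hc[0] == pytest.approx(10.0)
        assert m.sd_hc[0] == pytest.approx(np.sqrt(2))
        assert m.mu_sz[0] == pytest.approx(6.0)
        assert m.sd_sz[0] == pytest.approx(np.sqrt(2))

    def test_refit_deterministic(self, rng):
        P = rng.normal(size=(12, 2))
        labels = np.array(["HC"] * 6 + ["SZ"] * 6)
        m1, m2 = fit_score_model(P, labels), fit_score_model(P, labels)
        assert np.array_equal(m1.mu_hc, m2.mu_hc)
        assert np.array_equal(m1.sd_sz, m2.sd_sz)

    def test_zero_variance_rejected(self):
        P = np.array([[1.0], [1.0], [2.0], [3.0]])
        with pytest.raises(FitError):
            fit_score_model(P, np.array(["HC", "HC", "SZ", "SZ"]))


class TestScoring:
    def test_hand_z_scores(self):
        P = np.array([[9.0], [11.0], [5.0], [7.0], [7.0]])
        labels = np.array(["HC", "HC", "SZ", "SZ", "SZ"])
        m = fit_score_model(P[:4], labels[:4])
        # mu_hc=10, sd=sqrt2, mu_sz=6, sd=sqrt2; x=7: |z_hc|-|z_sz| > 0 -> SZ
        s = score_subjects(m, P[4:])
        expected = abs((7 - 10) / np.sqrt(2)) - abs((7 - 6) / np.sqrt(2))
        assert s[0] == pytest.approx(expected)
        assert classify(s)[0] == "SZ"

    def test_prototype_subject_classified_home(self):
        P = np.array([[9.0], [11.0], [5.0], [7.0]])
        labels = np.array(["HC", "HC", "SZ", "SZ"])
        m = fit_score_model(P, labels)
        s = score_subjects(m, np.array([[10.0]]))  # exactly mu_HC
        assert s[0] < 0 and classify(s)[0] == "HC"

    def test_boundary_score_labeled_sz(self):
        assert classify(np.array([0.0]))[0] == "SZ"


class TestEvaluate:
    def test_hand_confusion_counts(self):
        # TP=2, TN=1, FP=1, FN=0
        scores = np.array([1.0, 2.0, 0.5, -1.0])
        labels = np.array(["SZ", "SZ", "HC", "HC"])
        m = evaluate(scores, labels)
        assert (m.TP, m.TN, m.FP, m.FN) == (2, 1, 1, 0)
        assert m.accuracy == pytest.approx(0.75)
        assert m.precision == pytest.approx(2 / 3)
        assert m.sensitivity == pytest.approx(1.0)
        assert m.specificity == pytest.approx(0.5)
        assert m.balanced_accuracy == pytest.approx(0.75)

    def test_balanced_accuracy_identity_random_tables(self, rng):
        for _ in range(30):
            n = 40
            scores = rng.normal(size=n)
            labels = rng.choice(["HC", "SZ"], size=n)
            if len(set(labels)) < 2:
                continue
            m = evaluate(scores, labels)
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2)

    def test_auc_exhaustive_pair_count(self):
        scores = np.array([0.1, 0.2, 0.15, 0.3])
        labels = np.array(["HC", "HC", "SZ", "SZ"])
        assert evaluate(scores, labels).auc == pytest.approx(3 / 4)

    def test_auc_matches_threshold_sweep(self, rng):
        scores = rng.normal(size=60)
        labels = rng.choice(["HC", "SZ"], size=60)
        got = mann_whitney_auc(scores[labels == "SZ"], scores[labels == "HC"])
        want = roc_auc_score((labels == "SZ").astype(int), scores)
        assert got == pytest.approx(want, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.choice(["HC", "SZ"], size=40)
        a = mann_whitney_auc(scores[labels == "SZ"], scores[labels == "HC"])
        t = np.exp(scores)  # strictly increasing
        b = mann_whitney_auc(t[labels == "SZ"], t[labels == "HC"])
        assert a == pytest.approx(b)

    def test_ppv_npv_symmetric_at_half_prevalence(self):
        for q in (0.6, 0.75, 0.9):
            ppv, npv = ppv_npv(q, q, 0.5)
            assert ppv == pytest.approx(q)
            assert npv == pytest.approx(q)

    def test_ppv_equals_raw_precision_at_sample_prevalence(self, rng):
        scores = rng.normal(size=40)
        labels = np.array(["HC"] * 20 + ["SZ"] * 20)
        m = evaluate(scores, labels, prevalence=0.5)
        if m.TP + m.FP > 0:
            assert m.ppv == pytest.approx(m.TP / (m.TP + m.FP))

    def test_roc_points_span_unit_square(self, rng):
        scores = rng.normal(size=30)
        labels = rng.choice(["HC", "SZ"], size=30)
        df = roc_points(scores, labels)
        assert df.iloc[0]["tpr"] == 0.0 and df.iloc[0]["fpr"] == 0.0
        assert df.iloc[-1]["tpr"] == 1.0 and df.iloc[-1]["fpr"] == 1.0


class TestCrossValidate:
    def test_perfect_separation_scores_one(self):
        P = np.concatenate([np.random.default_rng(0).normal(0, 0.1, 12),
                            np.random.default_rng(1).normal(10, 0.1, 12)])[:, None]
        labels = np.array(["HC"] * 12 + ["SZ"] * 12)
        means, _ = cross_validate(P, labels, k=6, repeats=2, seed=0)
        assert means["accuracy"] == pytest.approx(1.0)

    def test_label_shuffle_near_chance(self, rng):
        P = rng.normal(size=(36, 2))
        labels = rng.permutation(np.array(["HC"] * 18 + ["SZ"] * 18))
        means, _ = cross_validate(P, labels, k=6, repeats=10, seed=1)
        assert means["accuracy"] == pytest.approx(0.5, abs=0.12)

    def test_no_leakage_of_test_subjects(self, rng):
        """Moving a test subject far away must not move the fold's model."""
        P = rng.normal(size=(24, 1))
        labels = np.array(["HC"] * 12 + ["SZ"] * 12)
        _, folds1 = cross_validate(P, labels, k=6, repeats=1, seed=5)
        P2 = P.copy()
        # perturb one subject; folds where it is in TEST must yield the same
        # predictions for the other test subjects
        rng2 = np.random.default_rng(5)
        from fcsubnet.classifier import _stratified_folds
        folds = _stratified_folds(labels, 6, rng2, True)
        target = folds[0][0]
        P2[target] += 100.0
        m1 = fit_score_model(np.delete(P, folds[0], 0),
                             np.delete(labels, folds[0]))
        m2 = fit_score_model(np.delete(P2, folds[0], 0),
                             np.delete(labels, folds[0]))
        assert np.array_equal(m1.mu_hc, m2.mu_hc)
        assert np.array_equal(m1.sd_sz, m2.sd_sz)

    def test_fold_counts_and_determinism(self, rng):
        P = rng.normal(size=(24, 1))
        labels = np.array(["HC"] * 12 + ["SZ"] * 12)
        means1, folds1 = cross_validate(P, labels, k=6, repeats=3, seed=9)
        means2, folds2 = cross_validate(P, labels, k=6, repeats=3, seed=9)
        assert len(folds1) == 18
        assert means1 == means2
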