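"""Classifier machinery: AUC, CI, sensitivity, CV, differential hotspots."""

import numpy as np
import pandas as pd
import pytest

from cfhotspot import (
    CVConfig,
    auc_confidence_interval,
    cross_validate_svm,
    differential_hotspots,
    predict_open_chromatin,
    roc_auc,
    sensitivity_at_specificity,
)
from cfhotspot.simulate import simulate_feature_matrix


def brute_force_auc(labels, scores):
    """Pairwise-comparison AUC estimator with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_matches_pairwise_estimator(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            assert roc_auc(labels, scores) == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)

    def test_ci_zero_variance(self):
        s = auc_confidence_interval([0.9] * 10)
        assert (s.ci_low, s.ci_high) == (0.9, 0.9)

    def test_ci_margin_formula(self, rng):
        aucs = rng.normal(0.8, 0.05, 100)
        s = auc_confidence_interval(aucs)
        sd = aucs.std(ddof=1)
        assert s.se == pytest.approx(sd / 10)
        assert s.ci_high - s.mean_auc == pytest.approx(1.96 * sd / 10)
        assert s.ci_low <= s.mean_auc <= s.ci_high


class TestSensitivityAtSpecificity:
    def test_disjoint_distributions(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert sensitivity_at_specificity(scores, labels, 1.0) == 1.0

    def test_identical_distributions_near_zero(self, rng):
        scores = np.concatenate([rng.normal(size=2000), rng.normal(size=2000)])
        labels = np.repeat([0, 1], 2000)
        assert sensitivity_at_specificity(scores, labels, 1.0) < 0.01

    def test_matches_exhaustive_threshold_search(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        for spec in (1.0, 2 / 3, 1 / 3):
            best = 0.0
            for thr in np.unique(scores) - 1e-9:
                fpr = np.mean(scores[labels == 0] > thr)
                if 1 - fpr >= spec - 1e-12:
                    best = max(best, float(np.mean(scores[labels == 1] > thr)))
            assert sensitivity_at_specificity(scores, labels, spec) == pytest.approx(best)


class TestCrossValidation:
    def test_strong_effect_separates(self):
        """30 vs 30 with 500 hotspots shifted by 3 sd: near-perfect AUC."""
        shift = np.full(500, 3.0)
        m = simulate_feature_matrix({"cancer": 30, "healthy": 30}, 500, shifts={"cancer": shift}, seed=11)
        summary, scores = cross_validate_svm(m, CVConfig(folds=10, repeats=2, seed=0), case_label="cancer")
        assert summary.mean_auc >= 0.99

    def test_permuted_labels_at_chance(self, rng):
        m = simulate_feature_matrix({"cancer": 30, "healthy": 30}, 200, seed=12)
        summary, _ = cross_validate_svm(m, CVConfig(folds=5, repeats=10, seed=0), case_label="cancer")
        assert 0.4 <= summary.mean_auc <= 0.6

    def test_deterministic_under_seed(self):
        m = simulate_feature_matrix({"cancer": 15, "healthy": 25}, 100, shifts={"cancer": np.full(100, 0.5)}, seed=13)
        cfg = CVConfig(folds=5, repeats=2, seed=42)
        s1, sc1 = cross_validate_svm(m, cfg, case_label="cancer")
        s2, sc2 = cross_validate_svm(m, cfg, case_label="cancer")
        assert s1.mean_auc == s2.mean_auc
        pd.testing.assert_frame_equal(sc1, sc2)

    def test_downsampling_changes_training_only(self):
        """With unbalanced classes, downsampling keeps every sample scored."""
        m = simulate_feature_matrix({"cancer": 10, "healthy": 40}, 100, shifts={"cancer": np.full(100, 1.0)}, seed=14)
        _, scores = cross_validate_svm(m, CVConfig(folds=5, repeats=1, seed=0), case_label="cancer")
        assert set(scores["sample"]) == set(m.values.index)


class TestDifferentialHotspots:
    def test_null_yields_nothing(self):
        m = simulate_feature_matrix({"case": 20, "control": 20}, 400, seed=21)
        res = differential_hotspots(m, "case", "control")
        assert (res.table["hotspot_class"] != "none").sum() <= 2

    def test_planted_shifts_recovered_with_sign(self):
        """100 shifted hotspots of 1000: >=90 recovered, classes by sign."""
        shift = np.zeros(1000)
        shift[:50] = 1.5   # hypo-fragmented in cases -> class I
        shift[50:100] = -1.5  # hyper-fragmented -> class II
        m = simulate_feature_matrix({"case": 25, "control": 25}, 1000, shifts={"case": shift}, seed=22)
        res = differential_hotspots(m, "case", "control")
        cls = res.table.set_index("hotspot")["hotspot_class"]
        cols = m.values.columns
        hits = (cls[cols[:50]] == "I").sum() + (cls[cols[50:100]] == "II").sum()
        assert hits >= 90
        assert (cls[cols[:50]] == "II").sum() == 0
        assert (cls[cols[50:100]] == "I").sum() == 0

    def test_label_swap_antisymmetry(self):
        shift = np.zeros(300)
        shift[:30] = 2.0
        m = simulate_feature_matrix({"case": 15, "control": 15}, 300, shifts={"case": shift}, seed=23)
        fwd = differential_hotspots(m, "case", "control").table
        rev = differential_hotspots(m, "control", "case").table
        np.testing.assert_allclose(fwd["delta_z"], -rev["delta_z"])
        swapped = rev["hotspot_class"].map({"I": "II", "II": "I", "none": "none"})
        assert (fwd["hotspot_class"] == swapped).all()


class TestOpenChromatin:
    def test_labels_independent_of_features_at_chance(self, rng):
        X = rng.normal(size=(300, 17))
        y = rng.integers(0, 2, 300)
        s = predict_open_chromatin(X, y, folds=5, seed=0)
        assert 0.35 <= s.mean_auc <= 0.65

    def test_open_regions_separate(self):
        """Open regions (IFS -2 sd, GC/CpG-rich composition) are told
        apart from closed background regions."""
        from cfhotspot.simulate import simulate_open_chromatin_regions

        X, y = simulate_open_chromatin_regions(n_regions=300, ifs_shift=-2.0, seed=1)
        s = predict_open_chromatin(X, y, folds=5, seed=0)
        assert s.mean_auc >= 0.95

    def test_deterministic(self, rng):
        X = rng.normal(size=(200, 17))
        y = np.repeat([0, 1], 100)
        a = predict_open_chromatin(X, y, folds=5, seed=3)
        b = predict_open_chromatin(X, y, folds=5, seed=3)
        assert a.mean_auc == b.mean_auc
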