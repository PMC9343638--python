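"""Splitting, confusion metrics, kappa, AUC, crossover, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import fluoromap as fm


def auc_bruteforce(labels, scores):
    """O(n^2) pair enumeration: ties count half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_exact_class_counts(self):
        y = np.r_[np.ones(10, int), np.zeros(90, int)]
        tr, te = fm.stratified_split(y, 0.8, seed=0)
        assert y[te].sum() == 2 and y[tr].sum() == 8
        assert len(tr) + len(te) == 100
        assert set(tr).isdisjoint(te)

    def test_deterministic(self):
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        a = fm.stratified_split(y, 0.8, seed=5)
        b = fm.stratified_split(y, 0.8, seed=5)
        np.testing.assert_array_equal(a[0], b[0])

    def test_no_binomial_spread_across_draws(self):
        y = np.r_[np.ones(50, int), np.zeros(450, int)]
        counts = {int(y[fm.stratified_split(y, 0.8, seed=s)[1]].sum()) for s in range(50)}
        assert counts == {10}

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            fm.stratified_split(np.array([1, 0, 0, 0]), 0.8, seed=0)


class TestConfusionMetrics:
    def test_perfect(self):
        m = fm.confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert (m.sensitivity, m.specificity, m.balanced_accuracy) == (1, 1, 1)

    def test_all_negative_predictions(self):
        m = fm.confusion_metrics([0, 1, 1, 0], [0, 0, 0, 0])
        assert (m.sensitivity, m.specificity, m.balanced_accuracy) == (0, 1, 0.5)

    def test_hand_counted_confusion(self):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        pred = np.r_[np.ones(40, int), np.zeros(10, int), np.ones(20, int), np.zeros(30, int)]
        m = fm.confusion_metrics(labels, pred)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.balanced_accuracy == pytest.approx(0.7)

    def test_missing_class_flagged(self):
        m = fm.confusion_metrics([1, 1], [1, 0])
        assert m.missing_class and np.isnan(m.specificity)


class TestKappa:
    def test_printed_pair(self):
        assert fm.kappa_from_accuracy(0.82, 0.5) == pytest.approx(0.64)

    def test_accuracy_at_nir_is_zero(self):
        assert fm.kappa_from_accuracy(0.7, 0.7) == 0.0

    def test_perfect_accuracy_is_one(self):
        assert fm.kappa_from_accuracy(1.0, 0.5) == 1.0

    def test_nir_one_rejected(self):
        with pytest.raises(ValueError):
            fm.kappa_from_accuracy(0.9, 1.0)

    def test_balanced_subset_identity_two_acc_minus_one(self, rng):
        labels = np.repeat([0, 1], 40)
        pred = rng.integers(0, 2, 80)
        acc = (pred == labels).mean()
        k = fm.balanced_kappa(labels, pred, n_downsamples=10, seed=0)
        # test set already balanced: every down-sample is the full set
        assert k == pytest.approx(fm.kappa_from_accuracy(acc, 0.5))
        assert k == pytest.approx(2 * acc - 1)

    def test_balanced_kappa_perfect_predictions(self, rng):
        labels = np.r_[np.ones(10, int), np.zeros(90, int)]
        assert fm.balanced_kappa(labels, labels, seed=1) == 1.0

    def test_balanced_kappa_reproducible(self, rng):
        labels = np.r_[np.ones(15, int), np.zeros(85, int)]
        pred = rng.integers(0, 2, 100)
        a = fm.balanced_kappa(labels, pred, seed=3)
        b = fm.balanced_kappa(labels, pred, seed=3)
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fm.balanced_kappa(np.ones(5, int), np.ones(5, int))


class TestAUC:
    def test_perfect_separation(self):
        assert fm.auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_independent_scores_near_half(self, rng):
        labels = rng.integers(0, 2, 5000)
        scores = rng.uniform(size=5000)
        assert abs(fm.auc(labels, scores) - 0.5) < 0.03

    def test_tie_case_matches_bruteforce_and_sklearn(self, rng):
        labels = np.array([0, 0, 1, 1, 0, 1])
        scores = np.array([0.2, 0.5, 0.5, 0.9, 0.1, 0.7])
        got = fm.auc(labels, scores)
        assert got == pytest.approx(auc_bruteforce(labels, scores))
        assert got == pytest.approx(roc_auc_score(labels, scores))

    def test_random_small_inputs_match_bruteforce(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 50))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            assert fm.auc(labels, scores) == pytest.approx(auc_bruteforce(labels, scores))

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 200)
        scores = rng.normal(size=200)
        assert fm.auc(labels, scores) == pytest.approx(fm.auc(labels, np.exp(scores)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fm.auc(np.zeros(5, int), np.arange(5.0))


class TestCrossover:
    def test_symmetric_distributions_give_half(self, rng):
        pos = rng.normal(0.7, 0.1, 4000)
        neg = 1.0 - pos  # mirror-symmetric about 0.5
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(4000, int), np.zeros(4000, int)]
        assert abs(fm.crossover_cutoff(labels, scores) - 0.5) < 0.02

    def test_transform_equivariance(self, rng):
        labels = rng.integers(0, 2, 300)
        scores = rng.uniform(size=300)
        t = fm.crossover_cutoff(labels, scores)
        t2 = fm.crossover_cutoff(labels, scores**3)
        # unique-minimizer case: the cutoff maps through the same transform
        assert t2 == pytest.approx(
            fm.crossover_cutoff(labels, scores) ** 3, abs=0.05
        ) or abs(t2 - t**3) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fm.crossover_cutoff(np.ones(4, int), np.arange(4.0))


class TestStratifiedMetrics:
    def test_single_stratum_equals_global(self, rng):
        labels = rng.integers(0, 2, 100)
        pred = rng.integers(0, 2, 100)
        out = fm.stratified_metrics(labels, pred, np.zeros(100))
        glob = fm.confusion_metrics(labels, pred)
        assert len(out) == 1
        assert out.loc[0, "balanced_accuracy"] == pytest.approx(glob.balanced_accuracy)

    def test_depth_bins_with_label_independent_depth(self, rng):
        n = 4000
        labels = rng.integers(0, 2, n)
        pred = np.where(rng.uniform(size=n) < 0.8, labels, 1 - labels)
        depth = rng.uniform(0, 1000, n)
        out = fm.stratified_metrics(labels, pred, depth, bin_edges=[0, 300, 600, 1000])
        assert len(out) == 3
        # accuracy has no depth structure: all bins near the 0.8 flip rate
        assert np.all(np.abs(out["balanced_accuracy"] - 0.8) < 0.05)

    def test_stratum_missing_class_flagged(self):
        labels = np.array([1, 1, 0, 1])
        pred = np.array([1, 0, 0, 1])
        strata = np.array(["a", "a", "b", "b"])
        out = fm.stratified_metrics(labels, pred, strata).set_index("stratum")
        assert bool(out.loc["a", "missing_class"])
        assert not bool(out.loc["b", "missing_class"])


class TestCrossValidate:
    def test_single_repetition_equals_manual_split(self, small_table, small_scenario):
        cfg = fm.ForestConfig(n_trees=31, seed=2)
        features = ["cov00", "cov01", "cov02"]
        report = fm.cross_validate(small_table, features, cfg, n_repetitions=1)
        y = small_table["label"].to_numpy(int)
        X = small_table[features].to_numpy(float)
        tr, te = fm.stratified_split(y, 0.8, seed=cfg.seed * 100003 + 0)
        from dataclasses import replace
        model = fm.BalancedForestModel(features, replace(cfg, seed=cfg.seed * 100003 + 0))
        model.fit(X[tr], y[tr])
        proba = model.predict_proba(X[te])
        m = fm.confusion_metrics(y[te], (proba > 0.5).astype(int))
        row = report.per_repetition.iloc[0]
        assert row["balanced_accuracy"] == pytest.approx(m.balanced_accuracy)
        assert row["auc"] == pytest.approx(fm.auc(y[te], proba))

    def test_balanced_accuracy_identity_and_mean_bounds(self, small_table):
        cfg = fm.ForestConfig(n_trees=31, seed=8)
        report = fm.cross_validate(small_table, ["cov00", "cov01", "cov02"], cfg, n_repetitions=5)
        df = report.per_repetition
        np.testing.assert_allclose(
            df["balanced_accuracy"], (df["sensitivity"] + df["specificity"]) / 2
        )
        mean_ba = report.means["balanced_accuracy"]
        assert df["balanced_accuracy"].min() <= mean_ba <= df["balanced_accuracy"].max()
        assert 0 <= report.crossover <= 1
        assert df["kappa"].between(-1, 1).all()

    def test_report_serializes(self, small_table):
        cfg = fm.ForestConfig(n_trees=11, seed=1)
        report = fm.cross_validate(small_table, ["cov00"], cfg, n_repetitions=2)
        d = report.to_dict()
        assert d["n_repetitions"] == 2
        assert set(d["mean"]) >= {"sensitivity", "specificity", "balanced_accuracy", "auc", "kappa"}
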