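from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from signseq.classification import (
    ClassifierSpec,
    SplitSpec,
    accuracy_vs_nir_test,
    bonferroni_adjust,
    knn_classify,
    knn_sweep,
    mlp_classify,
    nir_pvalue,
    no_information_rate,
    pca_project,
    sample_architectures,
    standardize_and_split,
    summarize_runs,
)
from signseq.synthetic import CorpusSpec, generate_labeled_dataset


def labeled_points(n_a=60, n_b=60, rho_a=0.7, rho_b=0.05, m_a=5, m_b=40,
                   len_a=15, len_b=30, seed=0):
    a = CorpusSpec(n_a, m_a, rho_a, length_median=len_a, label="A", seed=seed)
    b = CorpusSpec(n_b, m_b, rho_b, length_median=len_b, label="B", seed=seed + 1000)
    return generate_labeled_dataset(a, b)


@pytest.fixture(scope="module")
def separated():
    """Well-separated regimes: repetitive small-vocab vs diverse large-vocab."""
    df = labeled_points(n_a=120, n_b=120, seed=7)
    return standardize_and_split(df, SplitSpec(seed=7))


class TestSplit:
    def test_324_points_split_216_108(self):
        df = labeled_points(n_a=162, n_b=162, seed=1)
        split = standardize_and_split(df, SplitSpec(seed=1))
        assert len(split.y_train) == 216
        assert len(split.y_test) == 108

    def test_scaling_fitted_on_training_only(self, separated):
        assert np.allclose(separated.x_train.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(separated.x_train.std(axis=0), 1, atol=1e-9)

    def test_stratification_preserves_label_balance(self):
        df = labeled_points(n_a=100, n_b=50, seed=2)
        split = standardize_and_split(df, SplitSpec(seed=2))
        train_frac = (split.y_train == "A").mean()
        assert train_frac == pytest.approx(2 / 3, abs=0.02)

    def test_same_seed_same_partition(self):
        df = labeled_points(seed=3)
        s1 = standardize_and_split(df, SplitSpec(seed=5))
        s2 = standardize_and_split(df, SplitSpec(seed=5))
        assert np.array_equal(s1.x_test, s2.x_test)

    def test_more_than_two_labels_rejected(self):
        df = labeled_points()
        df.loc[df.index[:5], "corpus_label"] = "C"
        with pytest.raises(ValueError):
            standardize_and_split(df, SplitSpec())


class TestKNN:
    def test_coincident_training_point_wins_at_k1(self):
        # a test point sitting exactly on a training point takes its label
        df = labeled_points(seed=4)
        split = standardize_and_split(df, SplitSpec(seed=4))
        split.x_test = split.x_train[:10]
        split.y_test = split.y_train[:10].copy()
        run = knn_classify(split, ClassifierSpec("knn", k=1))
        assert run.accuracy == 1.0

    def test_separated_regimes_high_accuracy(self, separated):
        run = knn_classify(separated, ClassifierSpec("knn", k=5))
        assert run.accuracy >= 0.9

    def test_k_exceeding_training_size_rejected(self, separated):
        with pytest.raises(ValueError):
            knn_classify(separated, ClassifierSpec("knn", k=10_000))

    def test_sweep_adjusts_pvalues(self, separated):
        runs = knn_sweep(separated, k_grid=(1, 3, 5))
        assert len(runs) == 3
        for r in runs:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_monotone_power_in_separation(self):
        # widening the gap between regimes never hurts median KNN accuracy
        medians = []
        for rho_b in (0.6, 0.35, 0.05):  # increasing separation from rho_a=0.7
            accs = []
            for seed in range(10):
                df = labeled_points(rho_a=0.7, rho_b=rho_b, m_b=20, seed=100 + seed)
                split = standardize_and_split(df, SplitSpec(seed=seed))
                accs.append(knn_classify(split, ClassifierSpec("knn", k=5)).accuracy)
            medians.append(float(np.median(accs)))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9


class TestMLP:
    def test_sampled_architectures_respect_caps(self):
        for spec in sample_architectures(100, seed=0):
            assert 1 <= len(spec.architecture) <= 4
            assert all(1 <= w <= 5 for w in spec.architecture)

    def test_separable_data_high_median_accuracy(self, separated):
        runs = mlp_classify(separated, n_architectures=8, seed=0)
        assert len(runs) <= 8
        ok = [r.accuracy for r in runs if r.converged]
        assert np.median(ok) >= 0.95

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("mlp", architecture=(6,))
        with pytest.raises(ValueError):
            ClassifierSpec("mlp", architecture=(2, 2, 2, 2, 2))


class TestNIRTest:
    def test_nir_is_majority_fraction(self):
        assert no_information_rate(["A"] * 70 + ["B"] * 30) == 0.7

    def test_exact_binomial_tail_60_of_100(self):
        # sum_{x>=60} C(100,x) 0.5^100
        assert nir_pvalue(60, 100, 0.5) == pytest.approx(0.02844, abs=2e-5)

    def test_perfect_accuracy_tiny_pvalue(self):
        assert nir_pvalue(108, 108, 0.66) < 1e-15

    def test_accuracy_at_nir_not_significant(self):
        assert nir_pvalue(50, 100, 0.5) > 0.05

    def test_null_calibration_type_I_rate(self):
        # identically distributed classes: the NIR test should fire rarely
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            a = CorpusSpec(60, 8, 0.4, length_median=12, label="A", seed=seed)
            b = CorpusSpec(60, 8, 0.4, length_median=12, label="B", seed=5000 + seed)
            df = generate_labeled_dataset(a, b)
            split = standardize_and_split(df, SplitSpec(seed=seed))
            run = knn_classify(split, ClassifierSpec("knn", k=5))
            rejections += run.p_raw < 0.05
        assert rejections / n_seeds <= 0.10


class TestBonferroni:
    def test_capped_product(self):
        runs = [_dummy_run(p) for p in [0.01] * 100]
        assert all(r.p_adjusted == 1.0 for r in bonferroni_adjust(runs))

    def test_product(self):
        runs = [_dummy_run(1e-6) for _ in range(100)]
        assert bonferroni_adjust(runs)[0].p_adjusted == pytest.approx(1e-4)

    def test_single_run_unchanged(self):
        (run,) = bonferroni_adjust([_dummy_run(0.03)])
        assert run.p_adjusted == 0.03


def _dummy_run(p_raw):
    from signseq.classification import ClassificationRun

    return ClassificationRun(
        spec=ClassifierSpec("knn", k=1),
        accuracy=0.9, precision=0.9, recall=0.9, f1=0.9,
        n_test=10, n_correct=9, nir=0.5, p_raw=p_raw,
    )


class TestConfusionMatrixScores:
    def test_hand_computed_2x2(self):
        # truth: A A A B B B; predicted: A A B B B A
        # for positive class A: TP=2 FP=1 FN=1 TN=2
        from signseq.classification import SplitData, _scores
        from sklearn.preprocessing import StandardScaler

        split = SplitData(
            x_train=np.zeros((6, 4)), y_train=np.array(list("AAABBB")),
            x_test=np.zeros((6, 4)), y_test=np.array(list("AAABBB")),
            scaler=StandardScaler(), labels=("A", "B"),
        )
        run = _scores(split, np.array(list("AABBBA")), ClassifierSpec("knn", k=1))
        assert run.accuracy == pytest.approx(4 / 6)
        assert run.precision == pytest.approx(2 / 3)
        assert run.recall == pytest.approx(2 / 3)
        assert run.f1 == pytest.approx(2 / 3)


class TestPCA:
    def test_variance_ordering_and_orthonormal_loadings(self):
        df = labeled_points(seed=8)
        proj = pca_project(df)
        e1, e2 = proj.explained_variance_ratio
        assert e1 >= e2 >= 0
        L = proj.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(2), atol=1e-9)

    def test_sign_convention_H_loading_nonnegative(self):
        df = labeled_points(seed=9)
        proj = pca_project(df)
        assert proj.loadings.loc["H", "PC1"] >= 0

    def test_zero_variance_feature_named(self):
        df = labeled_points(seed=10)
        df["TTR"] = 0.5
        with pytest.raises(ValueError, match="TTR"):
            pca_project(df)

    def test_separated_regimes_split_along_pc1(self):
        df = labeled_points(n_a=150, n_b=150, seed=11)
        proj = pca_project(df)
        s = proj.scores
        a = s[s.corpus_label == "A"]["PC1"]
        b = s[s.corpus_label == "B"]["PC1"]
        pooled_sd = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 2 * pooled_sd


def test_summary_reports_percentage_significant():
    runs = bonferroni_adjust([_dummy_run(1e-8), _dummy_run(0.5)])
    summary = summarize_runs(runs)
    assert summary["n_converged"] == 2
    assert summary["pct_significant"] == pytest.approx(50.0)
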