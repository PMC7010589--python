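"""Boosted-tree classification, metrics, cross-validation, sweep."""

import hashlib
import math

import numpy as np
import pytest

import riemannfc as rf
from riemannfc.classify import (ComponentImportance, PipelineConfig,
                                SupportVectorBaseline, stratified_folds)


def chance_band(n: int, level: float = 0.95) -> tuple[float, float]:
    """Binomial 95% band around 50% accuracy, in percent."""
    half = 1.96 * math.sqrt(0.25 / n)
    return 100 * (0.5 - half), 100 * (0.5 + half)


class TestMetrics:
    def test_direct_ratios(self):
        m = rf.metrics(9, 1, 8, 2)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        assert m.accuracy == pytest.approx(0.85)

    def test_zero_denominator_is_nan_not_zero(self):
        m = rf.metrics(0, 0, 5, 0)
        assert math.isnan(m.sensitivity)
        assert m.specificity == 1.0
        assert m.accuracy == 1.0

    def test_all_correct(self):
        m = rf.metrics(7, 0, 7, 0)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rf.metrics(-1, 0, 1, 0)

    def test_cv_report_aggregates_fold_counts(self):
        folds = [rf.classify.FoldResult(3, 1, 4, 0),
                 rf.classify.FoldResult(2, 2, 3, 1)]
        report = rf.CvReport(folds=folds, config={}, seed=0)
        assert report.confusion == (5, 3, 7, 1)
        assert report.accuracy == pytest.approx(100 * 12 / 16)


class TestBoostedTrees:
    def test_perfect_separator_dominates_importance(self):
        rng = np.random.default_rng(0)
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 6))
        X[:, 2] = y * 2.0 - 1.0 + 0.01 * rng.standard_normal(n)
        _, imp = rf.train_boosted_trees(X, y, seed=0)
        assert imp.values[2] > 0.5
        assert imp.values.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="single class"):
            rf.train_boosted_trees(X, np.zeros(10, dtype=int))

    def test_constant_features_flagged(self):
        y = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="no informative splits"):
            _, imp = rf.train_boosted_trees(np.ones((20, 4)), y, seed=0)
        assert imp.values.sum() == pytest.approx(1.0)

    def test_importance_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ComponentImportance(np.array([0.5, 0.2]))
        with pytest.raises(ValueError, match="nonnegative"):
            ComponentImportance(np.array([1.5, -0.5]))


class TestSvmBaseline:
    def test_separable_toy_set_is_perfect(self):
        rng = np.random.default_rng(1)
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 4.0 - 2.0 + 0.1 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        clf = SupportVectorBaseline().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_same_fold_assignment_as_boosted_trees(self, planted_result):
        y = planted_result.cohort.indicator()
        folds_a = stratified_folds(y, 10, seed=3)
        folds_b = stratified_folds(y, 10, seed=3)
        digest = lambda folds: hashlib.sha256(
            b"".join(f.tobytes() for fold in folds for f in fold)).hexdigest()
        assert digest(folds_a) == digest(folds_b)


class TestCrossValidate:
    def test_planted_cohort_is_separable(self, planted_matrices,
                                         planted_result):
        report = rf.cross_validate(planted_matrices, planted_result.cohort,
                                   PipelineConfig(), seed=1)
        assert report.accuracy >= 85.0

    def test_null_cohort_at_chance(self, null_matrices, null_result):
        report = rf.cross_validate(null_matrices, null_result.cohort,
                                   PipelineConfig(), seed=1)
        lo, hi = chance_band(len(null_matrices))
        assert lo <= report.accuracy <= hi

    def test_label_shuffling_collapses_to_chance(self, planted_matrices,
                                                 planted_result):
        rng = np.random.default_rng(5)
        y = planted_result.cohort.indicator()
        shuffled = rng.permutation(y)
        report = rf.cross_validate(planted_matrices, shuffled,
                                   PipelineConfig(), seed=1)
        lo, hi = chance_band(len(y))
        assert lo <= report.accuracy <= hi

    def test_no_leakage_from_test_labels(self, small_cohort):
        # corrupting the labels of test-fold subjects must not change any
        # prediction: only training labels may influence the fitted models
        mats, y = small_cohort
        folds = stratified_folds(y, 4, seed=0)
        report_a = rf.cross_validate(mats, y, PipelineConfig(), folds=folds,
                                     seed=0)
        y_corrupt = y.copy()
        test_idx = np.asarray(folds[0][1])
        y_corrupt[test_idx] = 1 - y_corrupt[test_idx]
        report_b = rf.cross_validate(mats, y_corrupt, PipelineConfig(),
                                     folds=folds, seed=0)
        # fold 0 is the only fold whose training labels are untouched
        assert report_a.folds[0].predictions == report_b.folds[0].predictions

    def test_class_too_small_for_stratification(self, small_cohort):
        mats, y = small_cohort
        with pytest.raises(ValueError, match="stratify"):
            rf.cross_validate(mats, y, PipelineConfig(), k_folds=12, seed=0)

    @pytest.mark.parametrize("method", ["linear", "gaussian", "raw"])
    def test_baseline_methods_run_and_beat_chance(self, method,
                                                  planted_matrices,
                                                  planted_result):
        report = rf.cross_validate(planted_matrices, planted_result.cohort,
                                   PipelineConfig(method=method), seed=1)
        assert report.accuracy > 60.0

    def test_accuracy_monotone_in_effect_size(self):
        # 3-seed median CV accuracy must not decrease as the planted effect
        # grows (within Monte-Carlo noise)
        medians = []
        for effect in (0.0, 0.15, 0.3, 0.45):
            accs = []
            for seed in (1, 2, 3):
                res = rf.simulate_cohort(rf.SimulationConfig(
                    n_per_group=25, effect=effect, seed=seed))
                mats = [rf.fc_from_timeseries(s) for s in res.series]
                rep = rf.cross_validate(mats, res.cohort, PipelineConfig(),
                                        k_folds=5, seed=seed)
                accs.append(rep.accuracy)
            medians.append(float(np.median(accs)))
        for lo, hi in zip(medians, medians[1:]):
            assert hi >= lo - 5.0


class TestSweep:
    def test_single_cell_equals_direct_cross_validate(self, small_cohort):
        mats, y = small_cohort
        table = rf.sweep(mats, y, sigma_grid=["auto"], gamma_grid=[1.0],
                         k_folds=4, seed=0)
        direct = rf.cross_validate(mats, y, PipelineConfig(), k_folds=4,
                                   seed=0)
        assert len(table) == 1
        assert table.accuracy_pct[0] == pytest.approx(direct.accuracy)

    def test_empty_grid_rejected(self, small_cohort):
        mats, y = small_cohort
        with pytest.raises(ValueError, match="nonempty"):
            rf.sweep(mats, y, sigma_grid=[], gamma_grid=[1.0])

    def test_tiny_sigma_collapses_toward_chance(self, planted_matrices,
                                                planted_result):
        # sigma << default makes the kernel an identity matrix: features
        # carry no information and accuracy falls to chance
        sigma = rf.default_sigma(planted_matrices)
        report = rf.cross_validate(planted_matrices, planted_result.cohort,
                                   PipelineConfig(sigma=sigma / 100), seed=1)
        lo, hi = chance_band(len(planted_matrices))
        assert report.accuracy <= hi
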