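"""Fold plans, ROC/AUC, threshold selection, confusion metrics, CV harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breathprint.ann import MLPConfig
from breathprint.validate import (
    ConfusionCounts,
    confusion_counts,
    confusion_metrics,
    cross_validate,
    make_folds,
    metrics_table,
    roc_auc,
    select_threshold,
)


def _mann_whitney_auc(scores, y):
    """Brute-force pairwise oracle: P(case > control) with ties counted 1/2."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def _exhaustive_best_accuracy(scores, y):
    """Best achievable accuracy over every real cut-point (rule: score > t)."""
    best = 0.0
    for t in np.concatenate(([-np.inf], np.sort(scores), [np.inf])):
        pred = scores > t
        best = max(best, ((pred == (y == 1)).mean()))
    return best


class TestMakeFolds:
    def test_n10_gives_singletons(self):
        labels = np.array(["case"] * 5 + ["control"] * 5)
        plan = make_folds(labels, seed=0)
        assert len(plan.folds) == 10
        assert all(len(f) == 1 for f in plan.folds)

    def test_n163_partition_brute_force(self):
        labels = np.array(["case"] * 91 + ["control"] * 72)
        plan = make_folds(labels, seed=5)
        sizes = sorted(len(f) for f in plan.folds)
        assert set(sizes) <= {16, 17}
        all_idx = np.concatenate(plan.folds)
        assert sorted(all_idx) == list(range(163))  # disjoint + covering

    def test_stratified_proportions_within_one(self):
        labels = np.array(["case"] * 23 + ["control"] * 41)
        plan = make_folds(labels, seed=1, stratified=True)
        for f in plan.folds:
            n_case = (labels[f] == "case").sum()
            expected = len(f) * 23 / 64
            assert abs(n_case - expected) <= 1.0

    def test_same_seed_identical_plan(self):
        labels = np.array(["case", "control"] * 20)
        a = make_folds(labels, seed=9)
        b = make_folds(labels, seed=9)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_small_n_falls_back_to_loo(self):
        with pytest.warns(UserWarning, match="leave-one-out"):
            plan = make_folds(np.array(["case", "control"] * 3), seed=0)
        assert len(plan.folds) == 6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([]), seed=0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(10, 120), seed=st.integers(0, 9999),
           stratified=st.booleans())
    def test_property_exact_partition(self, n, seed, stratified):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random(n) < 0.4, "case", "control")
        if len(np.unique(labels)) < 2:
            labels[0] = "case"
        plan = make_folds(labels, seed=seed, stratified=stratified)
        all_idx = np.concatenate(plan.folds)
        assert sorted(all_idx) == list(range(n))
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([-0.9, -0.8, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        curve, auc = roc_auc(scores, y)
        assert auc == 1.0
        assert curve.fpr[0] == 0.0 and curve.tpr[-1] == 1.0

    def test_label_flip_symmetry(self, rng):
        scores = rng.standard_normal(30)
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        _, auc = roc_auc(scores, y)
        _, auc_flip = roc_auc(scores, 1 - y)
        assert auc_flip == pytest.approx(1.0 - auc, abs=1e-12)

    def test_matches_mann_whitney_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            y = (rng.random(n) < 0.5).astype(int)
            y[:2] = [0, 1]
            _, auc = roc_auc(scores, y)
            assert auc == pytest.approx(_mann_whitney_auc(scores, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestSelectThreshold:
    def test_separated_clusters(self):
        scores = np.array([-0.5, -0.4, 0.5, 0.6])
        y = np.array([0, 0, 1, 1])
        res = select_threshold(scores, y)
        assert res.accuracy == 1.0
        assert -0.4 < res.threshold < 0.5

    def test_all_identical_scores(self):
        scores = np.zeros(10)
        y = np.array([1] * 7 + [0] * 3)
        res = select_threshold(scores, y)
        assert res.accuracy == 0.7  # majority class

    def test_equality_classified_negative(self):
        scores = np.array([0.3, 0.3, 0.7])
        y = np.array([0, 0, 1])
        counts = confusion_counts(scores, y, threshold=0.3)
        assert counts.tn == 2 and counts.tp == 1 and counts.fp == 0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            scores = np.round(rng.uniform(-0.99, 0.99, 50), 2)
            y = (rng.random(50) < 0.5).astype(int)
            y[:2] = [0, 1]
            res = select_threshold(scores, y)
            assert res.accuracy == pytest.approx(
                _exhaustive_best_accuracy(scores, y), abs=1e-12
            )

    def test_tie_broken_by_youden_then_smallest(self):
        # two thresholds reach accuracy 3/4; J differs
        scores = np.array([-0.8, -0.2, 0.2, 0.8])
        y = np.array([0, 1, 0, 1])
        res = select_threshold(scores, y)
        best = _exhaustive_best_accuracy(scores, y)
        assert res.accuracy == best


class TestConfusionMetrics:
    def test_study_model1_counts(self):
        """The printed all-subsites confusion table: 72/91 cases and 45/72
        controls correct -> sensitivity 79%, specificity 63%, accuracy 72%."""
        out = confusion_metrics(ConfusionCounts(tp=72, fn=19, tn=45, fp=27))
        assert out["sensitivity"] == 79
        assert out["specificity"] == 63
        assert out["accuracy"] == 72

    def test_perfect_classifier(self):
        out = confusion_metrics(ConfusionCounts(tp=10, fn=0, tn=10, fp=0))
        assert all(out[k] == 100 for k in
                   ("sensitivity", "specificity", "accuracy", "ppv", "npv"))

    def test_undefined_ppv_flagged(self):
        out = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert out["ppv"] is None
        assert "ppv" in out["undefined"]

    def test_report_consistency(self, rng):
        for _ in range(10):
            c = ConfusionCounts(*(int(x) for x in rng.integers(0, 40, 4)))
            if c.total == 0:
                continue
            out = confusion_metrics(c)
            assert out["accuracy_frac"] == pytest.approx((c.tp + c.tn) / c.total)
            if c.tp + c.fn:
                assert out["sensitivity_frac"] == pytest.approx(c.tp / (c.tp + c.fn))


class TestCrossValidate:
    def _toy(self, rng, n=40):
        # flattened (6, 4) slices with a label-dependent mean shift
        y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        X = rng.standard_normal((n, 24))
        X[: n // 2] += 1.5
        return X, y

    def test_every_sample_scored_once(self, rng):
        X, y = self._toy(rng)
        plan = make_folds(y, seed=0)
        cands = [("none", MLPConfig(epochs=50))]
        oof = cross_validate(X, y, plan, cands,
                             tucker_params={"ranks": (2, 2), "slice_shape": (6, 4)})
        assert np.isfinite(oof[0]).all()
        assert (np.abs(oof[0]) <= 1.0).all()

    def test_deterministic(self, rng):
        X, y = self._toy(rng)
        plan = make_folds(y, seed=3)
        cands = [("zscore_fiber", MLPConfig(epochs=50))]
        kw = dict(tucker_params={"ranks": (2, 2), "slice_shape": (6, 4)})
        a = cross_validate(X, y, plan, cands, **kw)
        b = cross_validate(X, y, plan, cands, **kw)
        np.testing.assert_array_equal(a[0], b[0])

    def test_single_class_fold_skipped_with_warning(self, rng):
        X, y = self._toy(rng, n=20)
        # degenerate plan: fold 0 holds every control
        from breathprint.validate import FoldPlan
        folds = [np.arange(10, 20), np.arange(0, 5), np.arange(5, 10)]
        plan = FoldPlan(n_samples=20, folds=folds, seed=0, stratified=False)
        with pytest.warns(UserWarning, match="single-class"):
            oof = cross_validate(X, y, plan, [("none", MLPConfig(epochs=20))],
                                 tucker_params={"ranks": (2, 2), "slice_shape": (6, 4)})
        assert np.isnan(oof[0][10:]).all()
        assert np.isfinite(oof[0][:10]).all()

    def test_leakage_contract_training_params_only(self, rng):
        """Held-out transforms must use training-fold statistics: verified by
        checking the fitted fiber scaling of a compressor refit on the
        training part only."""
        from breathprint.tucker import TuckerCompressor
        X, y = self._toy(rng)
        tr = np.arange(10, 40)
        comp = TuckerCompressor(ranks=(2, 2), scaling="zscore_fiber",
                                slice_shape=(6, 4))
        comp.fit(X[tr])
        np.testing.assert_allclose(
            comp.model_.scaling.mean.ravel(), X[tr].mean(axis=0), atol=1e-12
        )


def test_metrics_table_shape():
    from breathprint.validate import DiagnosticReport, ROCCurve
    counts = ConfusionCounts(tp=72, fn=19, tn=45, fp=27)
    rep = DiagnosticReport(
        model_id="model1", n_cases=91, n_controls=72, threshold=0.07,
        counts=counts, metrics=confusion_metrics(counts), auc=0.75,
        roc=ROCCurve(np.array([1.0]), np.array([1.0]), np.array([1.0])),
        scaling_option="none", mlp_config=MLPConfig(),
    )
    text = metrics_table([rep])
    assert "Sensitivity\t79%" in text
    assert "AUC\t0.75" in text


def test_run_models_skips_empty_subsites():
    """A cohort with oral cases only yields model1 + model2; the oropharynx
    and glottis models are skipped with warnings."""
    from breathprint.simulate import CohortDesign, simulate_cohort
    from breathprint.validate import run_models

    cohort = simulate_cohort(
        CohortDesign(n_cases_by_subsite={"oral": 8}, n_controls=8,
                     n_devices=1, seed=6)
    )
    with pytest.warns(UserWarning, match="skipped"):
        reports = run_models(
            cohort, candidates=[("zscore_fiber", MLPConfig(epochs=60))], seed=6
        )
    assert [r.model_id for r in reports] == ["model1", "model2"]
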