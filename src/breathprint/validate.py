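"""Leave-10%-out cross-validation, ROC/threshold selection and reporting.

The validation harness mirrors the study design: for each case-control
model the full compress -> scale -> train chain is refit inside every
training fold (the Tucker factors and all scaling parameters are estimated
on the training fold only), each held-out sample receives exactly one
out-of-fold score per candidate, and the pooled out-of-fold scores drive
ROC construction, accuracy-maximizing threshold selection and the
confusion-matrix metrics. Pooled post-hoc threshold selection matches how
the study reports a single threshold per model; the optimism this
introduces is flagged in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .ann import (
    MLPConfig,
    BreathNet,
    FeatureScaler,
    TENSOR_LEVEL_OPTIONS,
    select_model,
)
from .simulate import Cohort
from .tucker import TuckerCompressor, measurement_slice

MODEL_SUBSETS = {
    "model1": None,  # all subsites
    "model2": "oral",
    "model3": "oropharynx",
    "model4": "glottis",
}


@dataclass
class FoldPlan:
    """An exact partition of sample indices into near-equal folds."""

    n_samples: int
    folds: list[np.ndarray]
    seed: int
    stratified: bool


def make_folds(labels, seed: int = 0, stratified: bool = True,
               n_folds: int = 10) -> FoldPlan:
    """Leave-10%-out fold plan: 10 near-equal folds (leave-one-out if n < 10).

    Stratified plans deal each class's shuffled members to folds through a
    single running cursor, so per-fold totals and per-fold class counts both
    stay within one sample of perfectly even.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n == 0:
        raise ValueError("empty labels")
    if n < n_folds:
        warnings.warn(
            f"n={n} < {n_folds}; falling back to leave-one-out", stacklevel=2
        )
        n_folds = n
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    cursor = 0
    groups = [np.flatnonzero(labels == v) for v in np.unique(labels)] if stratified \
        else [np.arange(n)]
    for idx in groups:
        idx = rng.permutation(idx)
        for i in idx:
            assignment[i] = cursor % n_folds
            cursor += 1
    folds = [np.flatnonzero(assignment == f) for f in range(n_folds)]
    return FoldPlan(n_samples=n, folds=folds, seed=seed, stratified=stratified)


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending cut-points
    tpr: np.ndarray
    fpr: np.ndarray


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """ROC curve over all distinct cut-points and trapezoidal AUC.

    Tied scores collapse to a single cut-point (a diagonal ROC segment), so
    the AUC equals the Mann-Whitney statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr), float(
        _trapezoid_auc(fpr, tpr)
    )


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        return (labels == "case").astype(int)
    return (np.asarray(labels, dtype=float) > 0).astype(int)


@dataclass
class ThresholdResult:
    threshold: float
    accuracy: float
    youden: float


def select_threshold(scores, labels) -> ThresholdResult:
    """Accuracy-maximizing threshold under the rule score > threshold -> positive.

    Candidates are the midpoints of adjacent distinct sorted scores plus the
    endpoints -1 and +1; ties on accuracy are broken by Youden's J, then by
    the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(scores_labels_check(scores, labels))
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        ([-1.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0])
    )
    pred = scores[None, :] > candidates[:, None]  # (n_cand, n)
    tp = (pred & (y == 1)).sum(axis=1)
    tn = (~pred & (y == 0)).sum(axis=1)
    acc = (tp + tn) / y.size
    sens = tp / n_pos
    spec = tn / n_neg
    youden = sens + spec - 1.0
    order = np.lexsort((candidates, -youden, -acc))
    best = order[0]
    return ThresholdResult(
        threshold=float(candidates[best]),
        accuracy=float(acc[best]),
        youden=float(youden[best]),
    )


def scores_labels_check(scores, labels):
    labels = np.asarray(labels)
    if labels.shape[0] != np.asarray(scores).shape[0]:
        raise ValueError("scores and labels must align")
    return labels


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts under the rule score > threshold -> positive (equality -> negative)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pred = scores > threshold
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity/specificity/accuracy/PPV/NPV from confusion counts.

    Full-precision fractions are retained under ``*_frac``; display values
    are percentages rounded half-up to whole percent. A zero-denominator
    rate is reported as None with its name listed under ``undefined``.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    c = counts
    rates = {
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "accuracy": (c.tp + c.tn, c.total),
        "ppv": (c.tp, c.tp + c.fp),
        "npv": (c.tn, c.tn + c.fn),
    }
    out: dict = {"undefined": []}
    for name, (num, den) in rates.items():
        if den == 0:
            out[f"{name}_frac"] = None
            out[name] = None
            out["undefined"].append(name)
        else:
            frac = num / den
            out[f"{name}_frac"] = frac
            out[name] = _round_half_up(100.0 * frac)
    return out


@dataclass
class DiagnosticReport:
    """Everything the study reports per model, from pooled out-of-fold scores."""

    model_id: str
    n_cases: int
    n_controls: int
    threshold: float
    counts: ConfusionCounts
    metrics: dict
    auc: float
    roc: ROCCurve
    scaling_option: str
    mlp_config: MLPConfig
    n_missing_scores: int = 0
    note: str = (
        "threshold selected post hoc on pooled out-of-fold scores; "
        "reported accuracy is optimistic to that extent"
    )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "threshold": round(self.threshold, 6),
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
            "sensitivity_pct": self.metrics["sensitivity"],
            "specificity_pct": self.metrics["specificity"],
            "accuracy_pct": self.metrics["accuracy"],
            "ppv_pct": self.metrics["ppv"],
            "npv_pct": self.metrics["npv"],
            "auc": round(self.auc, 2),
            "auc_full": self.auc,
            "scaling_option": self.scaling_option,
            "hidden_units": self.mlp_config.hidden_units,
            "n_missing_scores": self.n_missing_scores,
            "note": self.note,
        }


def metrics_table(reports: list[DiagnosticReport]) -> str:
    """Plain-text table: Sensitivity/Specificity/Accuracy/AUC x model."""
    header = "\t" + "\t".join(r.model_id for r in reports)
    rows = [header]
    for name, key in (
        ("Sensitivity", "sensitivity"),
        ("Specificity", "specificity"),
        ("Accuracy", "accuracy"),
    ):
        vals = [
            "NA" if r.metrics[key] is None else f"{r.metrics[key]}%" for r in reports
        ]
        rows.append(name + "\t" + "\t".join(vals))
    rows.append("AUC\t" + "\t".join(f"{r.auc:.2f}" for r in reports))
    return "\n".join(rows)


def _build_stage_estimators(option: str, cfg: MLPConfig, tucker_params: dict,
                            seed: int):
    tensor_scaling = option if option in TENSOR_LEVEL_OPTIONS else "none"
    feature_option = "none" if option in TENSOR_LEVEL_OPTIONS else option
    compressor = TuckerCompressor(scaling=tensor_scaling, **tucker_params)
    scaler = FeatureScaler(feature_option)
    net = BreathNet(
        hidden_units=cfg.hidden_units,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        alpha=cfg.alpha,
        random_state=seed,
    )
    return compressor, scaler, net


def cross_validate(
    X,
    y,
    plan: FoldPlan,
    candidates: list[tuple[str, MLPConfig]],
    tucker_params: dict | None = None,
) -> dict:
    """Out-of-fold scores per candidate under the leakage contract.

    ``X`` holds flattened measurement slices (n, d2*d3); the Tucker
    compressor, the feature scaler and the network are all refit on each
    training fold. Candidates sharing the same tensor-level scaling share
    one Tucker fit per fold (identical by determinism). A training fold
    containing a single class is skipped with a warning; its samples keep
    NaN scores for that candidate.
    """
    X = np.asarray(X, dtype=float)
    y = _as_binary(y)
    tucker_params = tucker_params or {}
    scores = {i: np.full(plan.n_samples, np.nan) for i in range(len(candidates))}
    for fold_idx, test_idx in enumerate(plan.folds):
        train_mask = np.ones(plan.n_samples, dtype=bool)
        train_mask[test_idx] = False
        y_tr = y[train_mask]
        if y_tr.min() == y_tr.max():
            warnings.warn(
                f"fold {fold_idx}: single-class training set; fold skipped",
                stacklevel=2,
            )
            continue
        X_tr, X_te = X[train_mask], X[test_idx]
        compressor_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for ci, (option, cfg) in enumerate(candidates):
            tensor_scaling = option if option in TENSOR_LEVEL_OPTIONS else "none"
            if tensor_scaling not in compressor_cache:
                comp = TuckerCompressor(scaling=tensor_scaling, **tucker_params)
                comp.fit(X_tr)
                compressor_cache[tensor_scaling] = (
                    comp.transform(X_tr),
                    comp.transform(X_te),
                )
            F_tr, F_te = compressor_cache[tensor_scaling]
            feature_option = "none" if option in TENSOR_LEVEL_OPTIONS else option
            scaler = FeatureScaler(feature_option).fit(F_tr)
            net = BreathNet(
                hidden_units=cfg.hidden_units,
                epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                alpha=cfg.alpha,
                random_state=cfg.seed + fold_idx,
            )
            net.fit(scaler.transform(F_tr), np.where(y_tr == 1, 1.0, -1.0))
            scores[ci][test_idx] = net.predict(scaler.transform(F_te))
    return {i: scores[i] for i in range(len(candidates))}


DEFAULT_CANDIDATES: list[tuple[str, MLPConfig]] = [
    ("none", MLPConfig()),
    ("zscore_fiber", MLPConfig()),
    ("minmax_feature", MLPConfig()),
    ("unit_norm_per_measurement", MLPConfig()),
]


def evaluate_model(
    cohort: Cohort,
    model_id: str = "model1",
    candidates: list[tuple[str, MLPConfig]] | None = None,
    tucker_params: dict | None = None,
    seed: int = 0,
    n_folds: int = 10,
    stratified: bool = True,
) -> DiagnosticReport:
    """Run one case-control model end to end on a cohort.

    Subsets cases to the model's subsite (model1 keeps all), cross-validates
    every candidate, selects the best by pooled CV accuracy (ties: AUC,
    hidden units, scaling order) and reports ROC/threshold/confusion metrics
    from the selected candidate's pooled out-of-fold scores.
    """
    candidates = candidates if candidates is not None else DEFAULT_CANDIDATES
    subsite = MODEL_SUBSETS[model_id]
    keep = [
        m.label == "control" or subsite is None or m.subsite == subsite
        for m in cohort
    ]
    sub = cohort.subset(keep)
    labels = sub.labels
    n_cases = int((labels == "case").sum())
    n_controls = int((labels == "control").sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"{model_id}: needs at least one case and one control")

    X = np.stack([measurement_slice(m.tensor).ravel() for m in sub])
    plan = make_folds(labels, seed=seed, stratified=stratified, n_folds=n_folds)
    oof = cross_validate(X, labels, plan, candidates, tucker_params)

    cv_results = []
    for i in range(len(candidates)):
        s = oof[i]
        ok = np.isfinite(s)
        _, auc_i = roc_auc(s[ok], labels[ok])
        thr_i = select_threshold(s[ok], labels[ok])
        cv_results.append({"accuracy": thr_i.accuracy, "auc": auc_i})
    best = select_model(candidates, cv_results)

    s = oof[best]
    ok = np.isfinite(s)
    curve, auc_val = roc_auc(s[ok], labels[ok])
    thr = select_threshold(s[ok], labels[ok])
    counts = confusion_counts(s[ok], labels[ok], thr.threshold)
    return DiagnosticReport(
        model_id=model_id,
        n_cases=n_cases,
        n_controls=n_controls,
        threshold=thr.threshold,
        counts=counts,
        metrics=confusion_metrics(counts),
        auc=auc_val,
        roc=curve,
        scaling_option=candidates[best][0],
        mlp_config=candidates[best][1],
        n_missing_scores=int((~ok).sum()),
    )


def run_models(
    cohort: Cohort,
    candidates: list[tuple[str, MLPConfig]] | None = None,
    tucker_params: dict | None = None,
    seed: int = 0,
    model_ids: tuple[str, ...] = ("model1", "model2", "model3", "model4"),
) -> list[DiagnosticReport]:
    """The study's model battery: all-subsites plus one model per subsite.

    A model whose subsite has no cases in the cohort is skipped with a
    warning.
    """
    reports = []
    for model_id in model_ids:
        subsite = MODEL_SUBSETS[model_id]
        has_cases = any(
            m.label == "case" and (subsite is None or m.subsite == subsite)
            for m in cohort
        )
        if not has_cases:
            warnings.warn(f"{model_id}: no cases with subsite {subsite}; skipped",
                          stacklevel=2)
            continue
        reports.append(
            evaluate_model(
                cohort,
                model_id,
                candidates=candidates,
                tucker_params=tucker_params,
                seed=seed,
            )
        )
    return reports
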