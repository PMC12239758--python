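"""Stratified cross-validation driver and the binary diagnostic metric panel.

Metrics follow the usual conventions for imbalanced binary diagnosis:

- ROC AUC is the Mann-Whitney statistic P(s+ > s-) + 0.5·P(s+ = s-),
  computed from ranks so ties are handled exactly.
- PR AUC uses step-wise (non-linear) interpolation; linear interpolation of
  precision-recall points overestimates the area.
- 0/0 rates (e.g. precision with no predicted positives) are reported as 0
  and flagged as undefined rather than propagating NaN.
- The Youden index is max over thresholds of sensitivity + specificity − 1,
  equivalently the maximum vertical distance between the ROC curve and the
  diagonal.

Cross-validation metrics are computed per fold and averaged (mean ±
population SD); pooled-prediction metrics over the concatenated validation
sets are reported alongside for transparency. The mean ROC curve is the
vertical average of per-fold curves on a common 101-point FPR grid, with
an SD band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .classifiers import ModelConfig, predict_scores, train_model
from .ensemble import EnsembleWeights, compute_weights, ensemble_scores_soft, weighted_vote
from .errors import ParameterError, UndefinedMetricError
from .preprocess import PreprocessRecipe, fit_preprocessor, transform

MODEL_ORDER = ("LR", "SVM_linear", "GaussianNB", "FFNN")
ENSEMBLE_NAME = "Integrated"
ROC_GRID_POINTS = 101
INNER_WEIGHT_FRACTION = 0.2  # held out from the training fold to estimate vote weights


@dataclass
class ConfusionMatrix:
    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}


@dataclass
class FoldResult:
    """One cross-validation fold's validation-set outputs for every model."""

    fold_index: int
    train_ids: list[str]
    val_ids: list[str]
    y_true: np.ndarray
    model_scores: dict[str, np.ndarray]
    model_labels: dict[str, np.ndarray]
    weights: EnsembleWeights
    n_selected: int
    effective_dims: int


@dataclass
class MetricsReport:
    """Per-model and ensemble metric panel aggregated over folds."""

    models: dict[str, dict]
    n_folds: int
    n_samples: int
    bootstrap: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "n_samples": self.n_samples,
            "bootstrap": self.bootstrap,
            "models": self.models,
        }


# --------------------------------------------------------------------------
# fold construction
# --------------------------------------------------------------------------

def stratified_folds(
    labels: np.ndarray, n_folds: int = 5, seed: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified (train, validation) index pairs preserving class proportions.

    Every sample appears in exactly one validation fold, and each fold's
    class counts deviate from the global proportions by at most one sample
    per class.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        small = classes[np.argmin(counts)]
        raise ParameterError(
            f"class {small!r} has {counts.min()} samples, fewer than {n_folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(y.size), y)]


# --------------------------------------------------------------------------
# scalar metrics
# --------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    u = np.unique(y)
    if u.size != 2:
        raise UndefinedMetricError(f"metric needs both classes present, got classes {u}")
    return (y == u.max()).astype(int)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve with step-wise interpolation."""
    y = np.asarray(labels)
    if np.sum(y == np.max(np.unique(y))) == 0 or np.unique(y).size != 2:
        raise UndefinedMetricError("PR AUC needs at least one positive and one negative")
    y01 = _check_binary(y)
    return float(average_precision_score(y01, np.asarray(scores, dtype=np.float64)))


def confusion_and_rates(
    hard_labels: np.ndarray, labels: np.ndarray
) -> tuple[ConfusionMatrix, dict]:
    """2×2 confusion matrix plus accuracy/precision/recall/specificity/F1.

    Undefined 0/0 ratios are reported as 0 and listed under ``"undefined"``.
    """
    yhat = np.asarray(hard_labels).astype(int)
    y = np.asarray(labels).astype(int)
    if yhat.size != y.size:
        raise ParameterError(f"length mismatch: {yhat.size} predictions vs {y.size} labels")
    tp = int(np.sum((yhat == 1) & (y == 1)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    cm = ConfusionMatrix(tp, fp, tn, fn)
    undefined: list[str] = []

    def _rate(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = _rate(tp, tp + fp, "precision")
    recall = _rate(tp, tp + fn, "recall")
    specificity = _rate(tn, tn + fp, "specificity")
    accuracy = (tp + tn) / cm.total if cm.total else 0.0
    f1 = _rate(2 * tp, 2 * tp + fp + fn, "f1")
    rates = {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "undefined": undefined,
    }
    return cm, rates


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; any zero denominator factor → 0."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def youden_index(scores: np.ndarray, labels: np.ndarray) -> float:
    """Max over thresholds of sensitivity + specificity − 1 (max TPR − FPR)."""
    y = _check_binary(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=np.float64), drop_intermediate=False)
    return float(np.max(tpr - fpr))


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    metric: Callable[[np.ndarray, np.ndarray], float] = roc_auc,
    reps: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval over resampled (score, label) pairs.

    Resamples in which the metric is undefined (single class drawn) are
    discarded.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    stats: list[float] = []
    for _ in range(reps):
        idx = rng.integers(0, s.size, size=s.size)
        try:
            stats.append(metric(s[idx], y[idx]))
        except UndefinedMetricError:
            continue
    if not stats:
        raise UndefinedMetricError("metric undefined in every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# fold aggregation
# --------------------------------------------------------------------------

def _fold_panel(scores: np.ndarray, hard: np.ndarray, y: np.ndarray) -> tuple[dict, ConfusionMatrix]:
    cm, rates = confusion_and_rates(hard, y)
    panel = {
        "roc_auc": roc_auc(scores, y),
        "pr_auc": pr_auc(scores, y),
        "accuracy": rates["accuracy"],
        "precision": rates["precision"],
        "recall": rates["recall"],
        "specificity": rates["specificity"],
        "f1": rates["f1"],
        "mcc": mcc(cm),
        "youden": youden_index(scores, y),
    }
    return panel, cm


def aggregate_cv(
    fold_results: Sequence[FoldResult],
    bootstrap_reps: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> MetricsReport:
    """Aggregate per-fold results into the full metric report.

    Per-fold metrics are averaged with population SD; confusion matrices
    are averaged elementwise; the mean ROC curve is the vertical average on
    a common FPR grid; bootstrap CIs are percentile intervals on the pooled
    validation predictions.
    """
    if not fold_results:
        raise ParameterError("no fold results to aggregate")
    model_names = list(fold_results[0].model_scores.keys())
    grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    report_models: dict[str, dict] = {}
    rng_seed = seed
    for name in model_names:
        per_fold = []
        cms = []
        tprs = []
        pooled_scores = []
        pooled_hard = []
        pooled_y = []
        for fr in fold_results:
            s = fr.model_scores[name]
            h = fr.model_labels[name]
            panel, cm = _fold_panel(s, h, fr.y_true)
            per_fold.append(panel)
            cms.append(cm)
            y01 = _check_binary(fr.y_true)
            fpr, tpr, _ = roc_curve(y01, s, drop_intermediate=False)
            it = np.interp(grid, fpr, tpr)
            it[0] = 0.0
            tprs.append(it)
            pooled_scores.append(s)
            pooled_hard.append(h)
            pooled_y.append(fr.y_true)
        metric_names = per_fold[0].keys()
        summary = {
            m: {
                "mean": float(np.mean([p[m] for p in per_fold])),
                "sd": float(np.std([p[m] for p in per_fold])),
            }
            for m in metric_names
        }
        cm_mean = {
            key: float(np.mean([c.as_dict()[key] for c in cms])) for key in ("TP", "FP", "TN", "FN")
        }
        ps = np.concatenate(pooled_scores)
        ph = np.concatenate(pooled_hard)
        py = np.concatenate(pooled_y)
        pooled_panel, _ = _fold_panel(ps, ph, py)
        ci = {}
        if bootstrap_reps > 0:
            lo, hi = bootstrap_ci(ps, py, roc_auc, reps=bootstrap_reps, level=ci_level, seed=rng_seed)
            ci["roc_auc"] = [lo, hi]
            lo, hi = bootstrap_ci(ps, py, pr_auc, reps=bootstrap_reps, level=ci_level, seed=rng_seed)
            ci["pr_auc"] = [lo, hi]
        tprs_arr = np.vstack(tprs)
        report_models[name] = {
            "fold_mean": summary,
            "pooled": pooled_panel,
            "confusion_mean": cm_mean,
            "mean_roc": {
                "fpr": grid.tolist(),
                "tpr_mean": tprs_arr.mean(axis=0).tolist(),
                "tpr_sd": tprs_arr.std(axis=0).tolist(),
            },
            "ci": ci,
        }
    n_samples = int(sum(len(fr.val_ids) for fr in fold_results))
    return MetricsReport(
        models=report_models,
        n_folds=len(fold_results),
        n_samples=n_samples,
        bootstrap={"reps": bootstrap_reps, "level": ci_level, "seed": seed},
    )


# --------------------------------------------------------------------------
# cross-validation driver
# --------------------------------------------------------------------------

def _train_and_score(
    model_configs: Sequence[ModelConfig],
    Xt_train: np.ndarray,
    y_train: np.ndarray,
    Xt_val: np.ndarray,
) -> dict[str, np.ndarray]:
    out = {}
    for cfg in model_configs:
        model = train_model(cfg, Xt_train, y_train)
        out[cfg.kind] = predict_scores(model, Xt_val)
    return out


def _inner_weight_aucs(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    recipe: PreprocessRecipe,
    model_configs: Sequence[ModelConfig],
    seed: int,
) -> list[float]:
    """Per-model AUCs on an internal stratified hold-out of the training fold."""
    y_tr = y[train_idx]
    rng = np.random.default_rng(seed)
    hold: list[int] = []
    for cls in np.unique(y_tr):
        idx = np.flatnonzero(y_tr == cls)
        rng.shuffle(idx)
        n_hold = max(1, int(round(INNER_WEIGHT_FRACTION * idx.size)))
        hold.extend(idx[:n_hold])
    hold_arr = np.array(sorted(hold))
    inner_val = train_idx[hold_arr]
    inner_tr = np.setdiff1d(train_idx, inner_val)
    fitted, Xt_tr, y_aug = fit_preprocessor(X[inner_tr], y[inner_tr], recipe, seed=seed)
    Xt_va = transform(X[inner_val], fitted)
    scores = _train_and_score(model_configs, Xt_tr, y_aug, Xt_va)
    return [roc_auc(scores[cfg.kind], y[inner_val]) for cfg in model_configs]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    recipe: PreprocessRecipe | None = None,
    model_configs: Sequence[ModelConfig] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    weight_rule: str = "proportional",
    auc_source: str = "inner-validation",
    soft: bool = False,
    bootstrap_reps: int = 1000,
    ci_level: float = 0.95,
) -> tuple[list[FoldResult], MetricsReport]:
    """Run the full stratified k-fold pipeline and aggregate the metric panel.

    ``y`` must be binary (0/1). All preprocessing (SMOTE, scaling, LASSO,
    PCA) is fitted inside each training fold when the recipe scope is
    per-fold; the global scope fits scaling/LASSO/PCA once on the full
    table (SMOTE stays fold-internal) to mirror reports that quote a single
    selected-feature count per task.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ParameterError("cross_validate expects binary 0/1 labels")
    n = X.shape[0]
    ids = list(sample_ids) if sample_ids is not None else [f"S{i}" for i in range(n)]
    recipe = recipe or PreprocessRecipe()
    seed = int(seed)

    if model_configs is None:
        model_configs = [ModelConfig(kind=k, seed=seed + i) for i, k in enumerate(MODEL_ORDER)]

    folds = stratified_folds(y, n_folds=n_folds, seed=seed)

    fitted_global = None
    if recipe.scope == "global":
        from dataclasses import replace

        fitted_global, _, _ = fit_preprocessor(
            X, y, replace(recipe, smote=False), seed=seed
        )

    results: list[FoldResult] = []
    for f, (tr, va) in enumerate(folds):
        fold_seed = (seed * 100003 + 7919 * (f + 1)) % (2**31)
        fold_cfgs = [
            ModelConfig(
                kind=c.kind,
                seed=(fold_seed + j) % (2**31),
                lr_max_iterations=c.lr_max_iterations,
                svm_C=c.svm_C,
                nb_var_smoothing=c.nb_var_smoothing,
                ffnn_max_epochs=c.ffnn_max_epochs,
                ffnn_patience=c.ffnn_patience,
                ffnn_val_fraction=c.ffnn_val_fraction,
            )
            for j, c in enumerate(model_configs)
        ]

        if recipe.scope == "global":
            from .preprocess import smote_oversample

            Xt_tr_raw = transform(X[tr], fitted_global)
            Xt_va = transform(X[va], fitted_global)
            if recipe.smote:
                Xt_tr, y_aug = smote_oversample(
                    Xt_tr_raw, y[tr], neighbors=recipe.smote_neighbors, seed=fold_seed
                )
            else:
                Xt_tr, y_aug = Xt_tr_raw, y[tr]
            fitted = fitted_global
        else:
            fitted, Xt_tr, y_aug = fit_preprocessor(X[tr], y[tr], recipe, seed=fold_seed)
            Xt_va = transform(X[va], fitted)

        val_scores = _train_and_score(fold_cfgs, Xt_tr, y_aug, Xt_va)

        if auc_source == "inner-validation":
            aucs = _inner_weight_aucs(X, y, tr, recipe, fold_cfgs, seed=fold_seed)
        else:
            aucs = [roc_auc(val_scores[c.kind], y[va]) for c in fold_cfgs]
        weights = compute_weights(aucs, source=auc_source, rule=weight_rule)

        names = [c.kind for c in fold_cfgs]
        score_mat = np.column_stack([val_scores[m] for m in names])
        vote_mat = (score_mat > 0.5).astype(int)
        ens_labels, ens_scores = weighted_vote(vote_mat, weights)
        if soft:
            ens_scores = ensemble_scores_soft(score_mat, weights)
            ens_labels = (ens_scores > 0.5).astype(int)

        model_scores = {m: val_scores[m] for m in names}
        model_labels = {m: vote_mat[:, j] for j, m in enumerate(names)}
        model_scores[ENSEMBLE_NAME] = ens_scores
        model_labels[ENSEMBLE_NAME] = ens_labels

        results.append(
            FoldResult(
                fold_index=f + 1,
                train_ids=[ids[i] for i in tr],
                val_ids=[ids[i] for i in va],
                y_true=y[va],
                model_scores=model_scores,
                model_labels=model_labels,
                weights=weights,
                n_selected=int(fitted.metadata.get("n_selected", fitted.feature_subset.size)),
                effective_dims=fitted.effective_dims,
            )
        )

    report = aggregate_cv(
        results, bootstrap_reps=bootstrap_reps, ci_level=ci_level, seed=seed
    )
    return results, report
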