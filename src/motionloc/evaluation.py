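"""K-fold cross-validation and classification metrics.

The headline summary follows the row-normalized confusion matrix convention:
``mean_accuracy`` is the unweighted mean of per-class recalls (the diagonal of
the row-normalized matrix), not the overall hit rate.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold

from . import classifier as _classifier
from . import feature_refinery as _refinery
from .core_io import FeatureMatrix, MetricsReport, SignalWindow
from .errors import ParameterError, StratificationError, UndefinedMetricError
from .features_location import MfccConfig, extract_localization_features
from .features_motion import extract_physical_features

log = logging.getLogger(__name__)


def kfold_indices(
    labels: Sequence[str], k: int = 5, stratified: bool = True, seed: int = 0
) -> list[np.ndarray]:
    """K disjoint test-index sets partitioning all indices."""
    labels = list(labels)
    if k < 2:
        raise ParameterError("K must be >= 2")
    if stratified:
        counts = {c: labels.count(c) for c in set(labels)}
        small = {c: n for c, n in counts.items() if n < k}
        if small:
            raise StratificationError(
                f"classes too small for {k}-fold stratification: {small}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(len(labels)), labels)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(labels)))]


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_names: Sequence[str]
) -> tuple[np.ndarray, float]:
    """Row-normalized confusion matrix and its mean diagonal."""
    if len(y_true) != len(y_pred):
        raise ParameterError("y_true and y_pred lengths differ")
    unknown = (set(y_true) | set(y_pred)) - set(class_names)
    if unknown:
        raise ParameterError(f"labels outside class_names: {unknown}")
    counts = _sk_confusion(y_true, y_pred, labels=list(class_names)).astype(float)
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [c for c, s in zip(class_names, row_sums) if s == 0]
        raise UndefinedMetricError(f"classes with zero true samples: {empty}")
    normalized = counts / row_sums[:, None]
    return normalized, float(np.mean(np.diag(normalized)))


def prf(
    y_true: Sequence[str], y_pred: Sequence[str], class_names: Sequence[str]
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Per-class precision, recall and F1; zero denominators yield 0."""
    p, r, f, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_names), zero_division=0
    )
    for c, prec, supp in zip(class_names, p, support):
        pred_count = list(y_pred).count(c)
        if pred_count == 0 or supp == 0:
            log.warning("class %r: zero denominator in precision/recall", c)
    to_map = lambda arr: {c: float(v) for c, v in zip(class_names, arr)}
    return to_map(p), to_map(r), to_map(f)


def _rank_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties (equals trapezoidal ROC area)."""
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    ranks = rankdata(scores)
    return float((ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(
    y_true: Sequence[str], probabilities: np.ndarray, class_names: Sequence[str]
) -> dict[str, float]:
    """One-vs-rest AUC per class via the rank statistic."""
    y_true = np.asarray(list(y_true))
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape != (len(y_true), len(class_names)):
        raise ParameterError("probability matrix not aligned with class_names")
    if len(set(y_true)) < 2:
        raise UndefinedMetricError("AUC undefined for single-class truth")
    aucs = {}
    for j, c in enumerate(class_names):
        positives = y_true == c
        if positives.all() or not positives.any():
            raise UndefinedMetricError(f"AUC undefined for class {c!r}")
        aucs[c] = _rank_auc(probabilities[:, j], positives)
    return aucs


# ---------------------------------------------------------------------------
# feature extraction over window collections
# ---------------------------------------------------------------------------


def extract_features(
    windows: Sequence[SignalWindow], stream: str, config: dict | None = None
) -> FeatureMatrix:
    """Feature matrix for a window collection, for one stream."""
    config = config or {}
    names = None
    rows, labels, flags, ids = [], [], [], []
    for w in windows:
        if stream == "physical":
            n, v = extract_physical_features(
                w,
                entropy_bins=config.get("entropy_bins", 16),
                lpc_order=config.get("lpc_order", 12),
                n_lpcc=config.get("n_lpcc", 12),
                lpcc_channels=tuple(
                    config.get("lpcc_channels", ("acc_x", "acc_y", "acc_z"))
                ),
            )
        elif stream == "localization":
            n, v = extract_localization_features(
                w,
                mfcc_config=config.get("mfcc", MfccConfig()),
                min_prominence_factor=config.get("min_prominence_factor", 0.5),
                min_period_s=config.get("min_period_s", 0.25),
                jitter_floor_m=config.get("jitter_floor_m", 1.0),
            )
        else:
            raise ParameterError(f"unknown stream {stream!r}")
        if names is None:
            names = n
        rows.append(v)
        labels.append(w.label)
        flags.append(w.augmented)
        ids.append(w.window_id)
    return FeatureMatrix(
        feature_names=names or [],
        rows=np.asarray(rows) if rows else np.empty((0, 0)),
        labels=labels,
        augmented_flags=np.asarray(flags, dtype=bool),
        row_ids=ids,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def cross_validate(
    windows: Sequence[SignalWindow],
    stream: str,
    k: int = 5,
    seed: int = 0,
    augment: bool = True,
    k_segments: int = 3,
    variance_threshold: float = 0.0,
    feature_config: dict | None = None,
    mlp_config: "_classifier.MlpConfig | None" = None,
    return_folds: bool = False,
):
    """Stratified K-fold evaluation of the full pipeline.

    In every fold the refinery and the classifier are fitted on training
    windows only; minority-class augmentation (when enabled) happens inside the
    fold, on training windows, before feature extraction. Test predictions are
    pooled over folds into one MetricsReport.
    """
    windows = list(windows)
    labels = [w.label for w in windows]
    if any(l is None for l in labels):
        raise ParameterError("all windows must be labeled for cross-validation")
    class_names = sorted(set(labels))
    folds = kfold_indices(labels, k=k, stratified=True, seed=seed)

    y_true: list[str] = []
    y_pred: list[str] = []
    proba_rows: list[np.ndarray] = []
    base_cfg = mlp_config or _classifier.MlpConfig()

    for fold_no, test_idx in enumerate(folds):
        try:
            test_set = set(int(i) for i in test_idx)
            train_windows = [w for i, w in enumerate(windows) if i not in test_set]
            test_windows = [windows[int(i)] for i in test_idx]
            if augment:
                train_windows = _refinery.balance_classes(
                    train_windows,
                    k_segments=k_segments,
                    rng_seed=np.random.default_rng((seed + 1) * 1000 + fold_no),
                )
            train_fm = extract_features(train_windows, stream, feature_config)
            state = _refinery.fit_refinery(train_fm, variance_threshold)
            train_ready = _refinery.apply_refinery(train_fm, state)
            fold_cfg = _classifier.MlpConfig(
                hidden_sizes=base_cfg.hidden_sizes,
                batch_size=base_cfg.batch_size,
                max_epochs=base_cfg.max_epochs,
                patience=base_cfg.patience,
                validation_fraction=base_cfg.validation_fraction,
                learning_rate=base_cfg.learning_rate,
                min_improvement=base_cfg.min_improvement,
                seed=base_cfg.seed + fold_no,
            )
            model = _classifier.train(train_ready, fold_cfg)

            test_fm = extract_features(test_windows, stream, feature_config)
            test_ready = _refinery.apply_refinery(test_fm, state)
            fold_proba = _classifier.predict_proba(model, test_ready)
            fold_pred = _classifier.predict(model, test_ready)
        except Exception as exc:
            raise type(exc)(f"fold {fold_no}: {exc}") from exc

        # align probability columns with the global class order
        col = {c: j for j, c in enumerate(model.class_names)}
        aligned = np.zeros((len(test_windows), len(class_names)))
        for j, c in enumerate(class_names):
            if c in col:
                aligned[:, j] = fold_proba[:, col[c]]
        y_true.extend(w.label for w in test_windows)
        y_pred.extend(fold_pred)
        proba_rows.append(aligned)

    proba = np.vstack(proba_rows)
    conf, mean_acc = confusion(y_true, y_pred, class_names)
    precision, recall, f1 = prf(y_true, y_pred, class_names)
    aucs = roc_auc(y_true, proba, class_names)
    report = MetricsReport(
        class_names=class_names,
        confusion=conf,
        mean_accuracy=mean_acc,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=aucs,
        macro_auc=float(np.mean(list(aucs.values()))),
        n_samples=len(y_true),
    )
    if return_folds:
        return report, folds
    return report
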