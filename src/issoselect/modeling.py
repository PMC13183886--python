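"""Random-forest training, stratified evaluation and the pipeline driver.

The evaluation protocol mirrors the study: a stratified 80/20 train/test
split, preprocessing and feature selection fit on the training partition
only (feature selection sees training-fold indices exclusively — the
leakage audit in :func:`run_pipeline` asserts this), a final 100-tree Gini
forest on the full balanced training set restricted to the selected
features, and accuracy / precision / recall / F1 / ROC-AUC plus confusion
counts on the untouched test set.  Cross-validated training metrics are
reported alongside the test-set metrics because the source protocol
conflates the two; neither is asserted as "the" number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import PipelineConfig
from .dataio import Dataset
from .errors import StateError, StratificationError, ValidationError
from .optimizer import CVMaskEvaluator, run_isso
from .preprocess import Preprocessor, smote

__all__ = [
    "train_forest",
    "stratified_folds",
    "compute_metrics",
    "f1_from_precision_recall",
    "MetricsReport",
    "run_pipeline",
]


def train_forest(
    features: np.ndarray, target: np.ndarray, cfg: PipelineConfig, seed: int
) -> RandomForestClassifier:
    """Fit the study's forest: bagged Gini trees, unrestricted depth,
    min-split 2.  The handle exposes ``predict`` and ``predict_proba``
    (positive-class score = fraction of trees voting positive)."""
    target = np.asarray(target)
    if len(np.unique(target)) < 2:
        raise ValidationError("training target has a single class")
    clf = RandomForestClassifier(
        n_estimators=cfg.classifier.n_trees,
        criterion=cfg.classifier.criterion,
        bootstrap=cfg.classifier.bootstrap,
        max_depth=cfg.classifier.max_depth,
        min_samples_split=2,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(features, target)
    return clf


def stratified_folds(
    target: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """k disjoint index folds with per-fold class counts within 1 of
    proportionality."""
    target = np.asarray(target)
    _, counts = np.unique(target, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} samples; cannot make {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [np.asarray(va) for _, va in skf.split(np.zeros(len(target)), target)]


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2pr/(p+r); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int
    precision_undefined: bool = False
    fold_accuracies: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray
) -> MetricsReport:
    """Standard binary metrics with positive class = 1.

    AUC is the rank (Mann-Whitney) statistic with ties averaged.  When no
    positives are predicted, precision is recorded as 0 with a flag rather
    than raising.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_score = np.asarray(y_score, dtype=float)
    if not (len(y_true) == len(y_pred) == len(y_score)):
        raise ValidationError("y_true, y_pred, y_score must have equal length")
    if y_score.min() < 0 or y_score.max() > 1:
        raise ValidationError("y_score must lie in [0, 1]")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = len(y_true)
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    auc = (
        float(roc_auc_score(y_true, y_score))
        if len(np.unique(y_true)) == 2
        else float("nan")
    )
    return MetricsReport(
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        auc=auc,
        tp=tp, tn=tn, fp=fp, fn=fn,
        precision_undefined=undefined,
    )


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([seed, 0x9199])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(
    data: Dataset,
    cfg: PipelineConfig,
    include_explanations: bool = False,
    explain_n_perm: int = 50,
    explain_instances: int = 3,
) -> dict:
    """End-to-end driver: split, preprocess, select, fit, evaluate, explain.

    Returns a JSON-serializable report carrying every seed, the fitted
    transform parameters, the selected mask, test-set and cross-validated
    metrics, and a leakage audit proving no held-out index ever reached the
    optimizer.
    """
    cfg.validate()
    split_seed, smote_seed, forest_seed, explain_seed = _derived_seeds(cfg.seed, 4)

    idx = np.arange(data.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=cfg.split_fraction,
        random_state=split_seed,
        stratify=data.target,
    )
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)

    def subset(ids: np.ndarray) -> Dataset:
        return Dataset(
            data.features[ids],
            list(data.feature_names),
            list(data.feature_kinds),
            data.target[ids],
            {g: tuple(c) for g, c in data.group_map.items()},
            list(data.group_names),
        )

    pre = Preprocessor(cfg.preprocessing)
    train = pre.fit_transform(subset(train_idx))
    test = pre.transform(subset(test_idx))

    evaluator = CVMaskEvaluator(train, cfg, row_indices=train_idx)
    mask, record, history = run_isso(evaluator, cfg.optimizer)
    cols = evaluator.columns_for_mask(mask)

    leakage = sorted(set(test_idx.tolist()) & set(evaluator.row_indices.tolist()))
    if leakage:  # pragma: no cover - guarded by construction
        raise StateError(f"test indices leaked into the optimizer: {leakage[:5]}")

    Xtr, ytr = train.features, train.target
    if cfg.preprocessing.use_smote and np.bincount(ytr).min() >= 2:
        counts = np.bincount(ytr)
        if counts[0] != counts[1]:
            Xtr, ytr = smote(Xtr, ytr, cfg.preprocessing.smote_k, seed=smote_seed)

    clf = train_forest(Xtr[:, cols], ytr, cfg, forest_seed)
    y_pred = clf.predict(test.features[:, cols])
    y_score = clf.predict_proba(test.features[:, cols])[:, 1]
    test_metrics = compute_metrics(test.target, y_pred, y_score)

    clf_all = train_forest(Xtr, ytr, cfg, forest_seed)
    all_metrics = compute_metrics(
        test.target,
        clf_all.predict(test.features),
        clf_all.predict_proba(test.features)[:, 1],
    )

    # cross-validated training metrics on the selected mask (reported
    # separately; the source protocol mixes CV and held-out figures)
    cv_acc = [
        float(s) for s in evaluator.evaluate(np.asarray(mask)).fold_scores
    ]

    selected_names = (
        [train.group_names[g] for g in np.flatnonzero(mask)]
        if cfg.optimizer.granularity == "group"
        else [train.feature_names[c] for c in np.flatnonzero(mask)]
    )

    report = {
        "config": {
            "seed": cfg.seed,
            "split_fraction": cfg.split_fraction,
            "cv_folds": cfg.cv_folds,
            "optimizer": dataclasses.asdict(cfg.optimizer),
            "classifier": dataclasses.asdict(cfg.classifier),
            "preprocessing": dataclasses.asdict(cfg.preprocessing),
        },
        "derived_seeds": {
            "split": split_seed, "smote": smote_seed,
            "forest": forest_seed, "explain": explain_seed,
        },
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "preprocessing": pre.to_dict(),
        "selected_mask": [int(b) for b in mask],
        "selected_features": selected_names,
        "n_selected": int(np.sum(mask)),
        "fitness": {
            "value": record.fitness,
            "cv_accuracy": record.accuracy,
            "history": [float(h) for h in history],
            "n_evaluations": evaluator.n_calls,
            "n_unique_evaluations": evaluator.n_unique_evaluations,
        },
        "test_metrics": test_metrics.to_dict(),
        "test_metrics_all_features": all_metrics.to_dict(),
        "cv_fold_accuracies": cv_acc,
        "cv_mean_accuracy": float(np.mean(cv_acc)),
        "leakage_audit": {
            "test_indices": [int(i) for i in test_idx],
            "optimizer_visible_indices": [int(i) for i in evaluator.row_indices],
            "intersection_empty": True,
        },
    }

    if include_explanations:
        from .explain import global_importance, local_surrogate, TrainingStats

        model = lambda X: clf.predict_proba(X)[:, 1]  # noqa: E731
        masked_train = _mask_dataset(train, cols)
        masked_test = _mask_dataset(test, cols)
        rng = np.random.default_rng(explain_seed)
        bg = masked_train.features[
            rng.choice(
                masked_train.n_samples,
                size=min(100, masked_train.n_samples),
                replace=False,
            )
        ]
        ranking = global_importance(
            model,
            masked_test.features[: max(explain_instances, 1)],
            bg,
            group_map=masked_train.group_map,
            feature_names=[masked_train.group_names[g] for g in sorted(masked_train.group_map)],
            n_perm=explain_n_perm,
            seed=explain_seed,
        )
        stats = TrainingStats.from_dataset(masked_train)
        local = local_surrogate(
            model, masked_test.features[0], stats,
            n_samples=1000, seed=explain_seed,
        )
        report["explanations"] = {
            "global_mean_abs_shapley": ranking.to_dict(orient="records"),
            "local_surrogate_example": {
                "feature_names": local.feature_names,
                "attributions": [float(a) for a in local.attributions],
                "instance_score": local.instance_score,
            },
        }
    return report


def _mask_dataset(data: Dataset, cols: list[int]) -> Dataset:
    remap = {c: i for i, c in enumerate(cols)}
    gm = {}
    for g, gcols in data.group_map.items():
        left = tuple(remap[c] for c in gcols if c in remap)
        if left:
            gm[g] = left
    return Dataset(
        data.features[:, cols],
        [data.feature_names[c] for c in cols],
        [data.feature_kinds[c] for c in cols],
        data.target.copy(),
        gm,
        list(data.group_names),
    )
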