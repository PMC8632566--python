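"""Classification experiments with participant-based cross-validation.

The protocol per fold: split at the participant level (no individual in
both train and test), standardise features to zero mean / unit variance
using training-fold statistics only, rebalance the training rows only
(feature-based models; the label-only baselines see the raw training
label distribution), fit, and score the untouched test rows at a fixed
probability threshold.

Two evaluation modes:

* user-independent — one model pooled over all participants, folds split
  by participant;
* user-dependent — a personalised model per patient, five-fold
  stratified row-level cross-validation within that patient's own data,
  per-patient fold means then averaged across patients.

Model types: ``rf`` (random forest), ``majority_vote`` (constant
prediction of the training-majority label, random on exact ties) and
``random`` (uniform coin-flip labels).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .labeling import LabeledDataset
from .metrics import MetricSet, SummaryStat, metric_set, roc_curve, summarize_folds
from .resampling import ResampleConfig, apply_plan, plan_resampling

logger = logging.getLogger(__name__)

MODEL_TYPES = ("rf", "majority_vote", "random")
MODES = ("user_independent", "user_dependent")


@dataclasses.dataclass
class CVConfig:
    n_folds: int = 5
    decision_threshold: float = 0.5
    n_trees: int = 100
    model_seed: int = 0
    fold_seed: int = 0
    #: compute the (comparatively expensive) B10 per fold
    with_b10: bool = True

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclasses.dataclass
class Standardizer:
    """Per-feature location/scale fitted on training rows only."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


@dataclasses.dataclass
class FoldResult:
    fold_index: int
    test_index: np.ndarray
    y_true: np.ndarray
    scores: np.ndarray
    y_pred: np.ndarray
    standardizer: Standardizer | None
    metrics: MetricSet


@dataclasses.dataclass
class ExperimentResult:
    contrast_name: str
    model_type: str
    mode: str
    fold_metrics: list[MetricSet]
    summary: dict[str, SummaryStat]
    folds: list[FoldResult] = dataclasses.field(default_factory=list)
    roc_points: np.ndarray | None = None
    per_patient: pd.DataFrame | None = None
    n_rows: int = 0

    def mean_auc(self) -> float:
        return self.summary["auc"].mean


def clean_features(entries: pd.DataFrame) -> pd.DataFrame:
    """Drop call rows with any missing feature and zero-variance features.

    Column order is otherwise preserved.  Raises if nothing survives.
    """
    feature_cols = [c for c in entries.columns if c.startswith("f")]
    cleaned = entries.dropna(subset=feature_cols)
    if cleaned.empty:
        raise ValueError("feature cleaning removed every call entry")
    n_dropped = len(entries) - len(cleaned)
    if n_dropped:
        logger.info("dropped %d call entries with missing features", n_dropped)
    constant = [c for c in feature_cols if cleaned[c].nunique() == 1]
    if constant:
        logger.info("dropped %d zero-variance features: %s", len(constant), constant)
        cleaned = cleaned.drop(columns=constant)
        if not any(c.startswith("f") for c in cleaned.columns):
            raise ValueError("feature cleaning removed every feature column")
    return cleaned.reset_index(drop=True)


def _child_seed(master: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(master), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def make_participant_folds(
    participant_ids: Sequence[str], n_folds: int, fold_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Participant-level partition into n_folds test sets (sizes differ by
    at most one participant); returns (train_ids, test_ids) per fold."""
    ids = np.unique(np.asarray(participant_ids))
    if len(ids) < n_folds:
        raise ValueError(
            f"{len(ids)} participants cannot be split into {n_folds} folds"
        )
    rng = np.random.default_rng(fold_seed)
    order = rng.permutation(ids)
    test_sets = np.array_split(order, n_folds)
    folds = []
    for test in test_sets:
        train = np.setdiff1d(ids, test)
        folds.append((train, np.sort(test)))
    return folds


def fit_standardizer(X_train: np.ndarray) -> Standardizer:
    """Zero-mean / unit-variance parameters (population variance).

    A feature constant within the training fold keeps scale 1 so it maps
    to 0 rather than NaN.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ValueError("empty training matrix")
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return Standardizer(mean=mean, scale=scale)


def apply_standardizer(standardizer: Standardizer, X: np.ndarray) -> np.ndarray:
    return standardizer.transform(X)


class _ConstantClassifier:
    """Degenerate stand-in when a training fold contains one class."""

    def __init__(self, label: int):
        self.label = int(label)

    def predict_proba(self, X) -> np.ndarray:
        p = np.zeros((len(X), 2))
        p[:, self.label] = 1.0
        return p


def fit_rf(X_train: np.ndarray, y_train: np.ndarray, config: CVConfig, seed: int):
    """Random-forest ensemble (bootstrap subsamples, random feature
    subsets); degenerates to constant prediction on single-class folds."""
    if len(X_train) == 0:
        raise ValueError("empty training set")
    classes = np.unique(y_train)
    if len(classes) < 2:
        logger.warning(
            "single-class training fold: fitting constant classifier (%d)",
            classes[0],
        )
        return _ConstantClassifier(classes[0])
    return RandomForestClassifier(
        n_estimators=config.n_trees, random_state=seed
    ).fit(X_train, y_train)


def majority_vote_baseline(
    train_labels: np.ndarray, test_size: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Constant prediction of the training-majority class (score 1.0 for
    the predicted class); an exact tie yields per-row random labels."""
    train_labels = np.asarray(train_labels, dtype=int)
    if len(train_labels) == 0:
        raise ValueError("empty training labels")
    n_pos = int(train_labels.sum())
    n_neg = len(train_labels) - n_pos
    if n_pos == n_neg:
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, test_size)
    else:
        labels = np.full(test_size, int(n_pos > n_neg))
    return labels, labels.astype(float)


def random_baseline(test_size: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-random class labels; scores 0/1 accordingly."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, test_size)
    return labels, labels.astype(float)


def _score_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    model_type: str,
    cv: CVConfig,
    resample: ResampleConfig,
    seed: int,
) -> tuple[np.ndarray, Standardizer | None]:
    """Train-only standardisation + rebalancing + model fit; test scores."""
    if model_type == "majority_vote":
        _, scores = majority_vote_baseline(y_train, len(X_test), seed)
        return scores, None
    if model_type == "random":
        _, scores = random_baseline(len(X_test), seed)
        return scores, None
    if model_type != "rf":
        raise ValueError(f"unknown model type {model_type!r}")

    standardizer = fit_standardizer(X_train)
    X_tr = standardizer.transform(X_train)
    X_te = standardizer.transform(X_test)
    counts = np.bincount(y_train, minlength=2)
    if counts.min() == 0:
        clf = fit_rf(X_tr, y_train, cv, seed)
    else:
        minority, majority = int(np.argmin(counts)), int(np.argmax(counts))
        if counts[0] == counts[1]:
            minority, majority = 0, 1
        fold_resample = dataclasses.replace(resample, seed=seed)
        plan = plan_resampling(counts[minority], counts[majority], fold_resample)
        X_bal, y_bal = apply_plan(X_tr, y_train, plan, fold_resample)
        logger.debug(
            "fold rebalancing: branch=%s minority %d->%d majority %d->%d",
            plan.branch,
            plan.n_minority,
            plan.n_minority + plan.n_synthetic_minority,
            plan.n_majority,
            plan.n_majority_keep,
        )
        clf = fit_rf(X_bal, y_bal, cv, seed)
    scores = clf.predict_proba(X_te)
    # column for the positive class (constant classifiers are 2-column)
    if isinstance(clf, _ConstantClassifier):
        scores = scores[:, 1]
    else:
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        scores = scores[:, pos_col]
    return scores, standardizer


def _pooled_roc(folds: list[FoldResult]) -> np.ndarray | None:
    """ROC points aggregated over all test rows of all folds."""
    y = np.concatenate([f.y_true for f in folds])
    s = np.concatenate([f.scores for f in folds])
    if len(np.unique(y)) < 2:
        return None
    return roc_curve(s, y)


def run_user_independent(
    dataset: LabeledDataset,
    model_type: str = "rf",
    cv: CVConfig | None = None,
    resample: ResampleConfig | None = None,
    fold_unit: str = "participant",
) -> ExperimentResult:
    """Pooled model over all participants, cross-validated by participant.

    ``fold_unit='row'`` deliberately breaks the participant grouping
    (row-level folds) to demonstrate identity leakage; every participant
    then typically appears on both sides of the split and the apparent
    AUC inflates.
    """
    cv = cv or CVConfig()
    resample = resample or ResampleConfig()
    cv.validate()
    resample.validate()
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")

    X = dataset.X
    y = dataset.y
    pids = dataset.participants
    if len(np.unique(y)) < 2:
        raise ValueError("dataset has a single class")

    if fold_unit == "participant":
        folds_ids = make_participant_folds(pids, cv.n_folds, cv.fold_seed)
        fold_indices = [
            (np.flatnonzero(np.isin(pids, tr)), np.flatnonzero(np.isin(pids, te)))
            for tr, te in folds_ids
        ]
    elif fold_unit == "row":
        rng = np.random.default_rng(cv.fold_seed)
        order = rng.permutation(len(y))
        fold_indices = [
            (np.setdiff1d(np.arange(len(y)), te), np.sort(te))
            for te in np.array_split(order, cv.n_folds)
        ]
    else:
        raise ValueError(f"unknown fold_unit {fold_unit!r}")

    fold_results: list[FoldResult] = []
    for k, (tr, te) in enumerate(fold_indices):
        if fold_unit == "participant":
            overlap = set(pids[tr]) & set(pids[te])
            assert not overlap, f"participant leakage in fold {k}: {overlap}"
        seed = _child_seed(cv.model_seed, k)
        scores, standardizer = _score_fold(
            X[tr], y[tr], X[te], model_type, cv, resample, seed
        )
        pred = (scores >= cv.decision_threshold).astype(int)
        metrics = metric_set(
            y[te], pred, scores, with_b10=cv.with_b10, b10_seed=seed
        )
        fold_results.append(
            FoldResult(k, te, y[te], scores, pred, standardizer, metrics)
        )

    fold_metrics = [f.metrics for f in fold_results]
    return ExperimentResult(
        contrast_name=dataset.contrast_name,
        model_type=model_type,
        mode="user_independent",
        fold_metrics=fold_metrics,
        summary=summarize_folds(fold_metrics),
        folds=fold_results,
        roc_points=_pooled_roc(fold_results),
        n_rows=len(y),
    )


def run_user_dependent(
    dataset: LabeledDataset,
    model_type: str = "rf",
    cv: CVConfig | None = None,
    resample: ResampleConfig | None = None,
) -> ExperimentResult:
    """Personalised model per patient, stratified row-level CV within each.

    Eligibility: at least 2 rows of each class and at least ``n_folds``
    rows in total; the fold count is reduced to the largest feasible
    k >= 2 (bounded by the minority count) when a strict five-fold split
    is impossible.  Ineligible patients are excluded and logged.  The
    summary averages the per-patient fold means across patients.
    """
    cv = cv or CVConfig()
    resample = resample or ResampleConfig()
    cv.validate()
    resample.validate()
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")

    frame = dataset.frame
    patient_rows: list[dict] = []
    patient_means: list[MetricSet] = []
    all_folds: list[FoldResult] = []

    for p_idx, (pid, sub) in enumerate(frame.groupby("participant_id", sort=True)):
        y = sub["label"].to_numpy(dtype=int)
        X = sub[dataset.feature_names].to_numpy(dtype=float)
        n_min = int(min((y == 0).sum(), (y == 1).sum()))
        if n_min < 2 or len(y) < cv.n_folds:
            logger.info(
                "patient %s ineligible for user-dependent CV "
                "(%d rows, minority class %d)",
                pid,
                len(y),
                n_min,
            )
            continue
        k = min(cv.n_folds, n_min)
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=_child_seed(cv.fold_seed, p_idx)
        )
        fold_metrics = []
        for f_idx, (tr, te) in enumerate(skf.split(X, y)):
            seed = _child_seed(cv.model_seed, p_idx, f_idx)
            scores, standardizer = _score_fold(
                X[tr], y[tr], X[te], model_type, cv, resample, seed
            )
            pred = (scores >= cv.decision_threshold).astype(int)
            metrics = metric_set(
                y[te], pred, scores, with_b10=cv.with_b10, b10_seed=seed
            )
            fold_metrics.append(metrics)
            all_folds.append(
                FoldResult(f_idx, te, y[te], scores, pred, standardizer, metrics)
            )
        per_patient_summary = summarize_folds(fold_metrics)
        mean_metrics = MetricSet(
            **{
                name: (
                    per_patient_summary[name].mean
                    if per_patient_summary[name].n > 0
                    else None
                )
                for name in MetricSet.FIELDS
            }
        )
        patient_means.append(mean_metrics)
        patient_rows.append(
            {
                "participant_id": pid,
                "n_rows": len(y),
                "n_folds": k,
                **{name: getattr(mean_metrics, name) for name in MetricSet.FIELDS},
            }
        )

    if not patient_means:
        raise ValueError("no patient eligible for user-dependent cross-validation")

    return ExperimentResult(
        contrast_name=dataset.contrast_name,
        model_type=model_type,
        mode="user_dependent",
        fold_metrics=patient_means,
        summary=summarize_folds(patient_means),
        folds=all_folds,
        roc_points=_pooled_roc(all_folds),
        per_patient=pd.DataFrame(patient_rows),
        n_rows=int(sum(r["n_rows"] for r in patient_rows)),
    )
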