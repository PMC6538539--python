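"""Balanced stratified cross-validation and macro-averaged metrics.

The evaluation protocol is 5-fold stratified cross-validation with, by
default, per-class balancing of each training split by undersampling to the
split's smallest class.  Per-fold accuracy, precision, recall and F1 are
macro-averaged with equal class weights (support-weighted averaging is
available side by side), and fold results are aggregated as Max/Ave/Min
triples per metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .records_io import LabelError, LabelScheme

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


class StratificationError(ValueError):
    """A class is too small to spread over the requested folds."""


@dataclass(frozen=True)
class MetricSet:
    """Accuracy plus averaged precision/recall/F1, each in [0, 1].

    ``averaging`` records how per-class values were combined:
    ``"macro_equal"`` weighs every class equally; ``"weighted_by_support"``
    weighs by true-class frequency.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str = "macro_equal"

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each record to one validation fold, plus balancing."""

    k: int
    assignments: np.ndarray  # record index -> fold id
    labels: np.ndarray
    balance_policy: str = "undersample"
    seed: int = 0

    def val_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        """Training indices for `fold`, balanced per ``balance_policy``.

        Under ``"undersample"``, each class in the training split is
        subsampled (without replacement, seeded per fold) to the split's
        smallest class count.
        """
        idx = np.flatnonzero(self.assignments != fold)
        if self.balance_policy == "none":
            return idx
        return undersample(idx, self.labels[idx], seed=self.seed * 1000 + fold)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("record_id,fold\n")
            for i, f in enumerate(self.assignments):
                fh.write(f"{i},{f}\n")
        return path


def undersample(indices: np.ndarray, labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Subsample `indices` so every class matches the smallest class count.

    Sampling is without replacement and seeded; the returned indices are
    sorted so output order does not depend on class order.
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    m = counts.min()
    keep: list[np.ndarray] = []
    for c in classes:
        members = indices[labels == c]
        keep.append(rng.choice(members, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def stratified_balanced_folds(
    labels: Sequence[str],
    k: int = 5,
    policy: str = "undersample",
    seed: int = 0,
) -> FoldPlan:
    """Stratified k-fold plan over `labels` with per-class proportions
    preserved within one record per fold.

    Raises :class:`StratificationError` naming any class with fewer than
    `k` members.
    """
    labels = np.asarray(labels)
    if policy not in ("undersample", "none"):
        raise ValueError(f"unknown balance policy {policy!r}")
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise StratificationError(
            f"classes {list(small)} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[val_idx] = fold
    return FoldPlan(
        k=k, assignments=assignments, labels=labels,
        balance_policy=policy, seed=seed,
    )


def compute_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    scheme: LabelScheme | Sequence[str] | None = None,
    averaging: str = "macro_equal",
) -> MetricSet:
    """Accuracy and averaged precision/recall/F1 from two label sequences.

    Per-class precision, recall and F1 come from the confusion matrix over
    the scheme's classes; a class with no predicted (or no true) positives
    scores 0 for the undefined quantity, with a logged warning.  Aggregation
    is equal-weight macro or support-weighted per `averaging`.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if averaging not in ("macro_equal", "weighted_by_support"):
        raise ValueError(f"unknown averaging {averaging!r}")
    if scheme is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.asarray(
            scheme.classes if isinstance(scheme, LabelScheme) else list(scheme)
        )
        seen = set(classes.tolist())
        for arr, kind in ((y_true, "true"), (y_pred, "predicted")):
            bad = [v for v in np.unique(arr) if v not in seen]
            if bad:
                raise LabelError(f"{kind} labels {bad} outside the scheme classes")
    average = "macro" if averaging == "macro_equal" else "weighted"
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=average, zero_division=0
    )
    p_cls, r_cls, _, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=None, zero_division=np.nan
    )
    if np.isnan(p_cls).any() or np.isnan(r_cls).any():
        logger.warning(
            "compute_metrics: undefined precision/recall for some class scored as 0"
        )
    return MetricSet(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        averaging=averaging,
    )


@dataclass(frozen=True)
class FoldReport:
    """Per-fold metrics with element-wise Max/Ave/Min aggregation."""

    folds: tuple[MetricSet, ...]

    @property
    def aggregate(self) -> dict[str, tuple[float, float, float]]:
        out = {}
        for m in METRIC_NAMES:
            values = np.array([getattr(f, m) for f in self.folds])
            out[m] = (float(values.max()), float(values.mean()), float(values.min()))
        return out

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "aggregate": {
                m: {"max": v[0], "ave": v[1], "min": v[2]}
                for m, v in self.aggregate.items()
            },
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2) + "\n", encoding="utf-8")
        return path


def aggregate_folds(metric_sets: Iterable[MetricSet]) -> FoldReport:
    """Collect per-fold metrics into a report with Max/Ave/Min triples."""
    folds = tuple(metric_sets)
    if not folds:
        raise ValueError("aggregate_folds requires at least one fold")
    return FoldReport(folds=folds)


def cross_validate(
    estimator,
    texts: Sequence,
    labels: Sequence[str],
    k: int = 5,
    policy: str = "undersample",
    seed: int = 0,
    averaging: str = "macro_equal",
    scheme: LabelScheme | None = None,
) -> FoldReport:
    """Run the full protocol: balanced stratified k-fold CV of `estimator`.

    The estimator is cloned per fold, fitted on the (balanced) training
    split and scored on the validation split.  Works for the convolutional
    model and the baseline pipelines alike.
    """
    labels = np.asarray(labels)
    texts = [getattr(t, "text", t) for t in texts]
    plan = stratified_balanced_folds(labels, k=k, policy=policy, seed=seed)
    fold_metrics = []
    for fold in range(k):
        tr = plan.train_indices(fold)
        va = plan.val_indices(fold)
        model = clone(estimator)
        if hasattr(model, "seed"):
            model.set_params(seed=seed * 100 + fold)
        elif hasattr(model, "random_state"):
            model.set_params(random_state=seed * 100 + fold)
        X_tr = [texts[i] for i in tr]
        X_va = [texts[i] for i in va]
        model.fit(X_tr, labels[tr])
        y_pred = model.predict(X_va)
        fold_metrics.append(
            compute_metrics(labels[va], y_pred, scheme=scheme, averaging=averaging)
        )
    return aggregate_folds(fold_metrics)


def report_table_csv(
    reports: dict, path: str | Path
) -> Path:
    """Write a rows-by-groups comparison table as CSV.

    `reports` maps a row name (e.g. ``"group_2"`` or ``"cnn/group_2"``) to a
    :class:`FoldReport`; cells are ``max/ave/min`` percent triples per metric.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("row," + ",".join(f"{m}_max,{m}_ave,{m}_min" for m in METRIC_NAMES) + "\n")
        for name, report in reports.items():
            agg = report.aggregate
            cells = []
            for m in METRIC_NAMES:
                cells += [f"{100 * v:.2f}" for v in agg[m]]
            fh.write(name + "," + ",".join(cells) + "\n")
    return path
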