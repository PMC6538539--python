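"""Hyperparameter sweeps, grid search and random search with trial accounting.

A sweep varies one hyperparameter over a value list while everything else
stays at a base configuration, recording the validation loss per value — the
classic one-dimensional regularization study (dropout 0.1–0.9, l2 1e-3–1e-6,
feature maps 50–1000, batch size 32–128).  Grid search enumerates the full
Cartesian product of a declared space; random search draws a fixed number of
seeded uniform samples (with replacement) from the same space.  Both select
the trial with minimal validation loss, and every trial is appended to a
JSON-lines log as it finishes so interrupted searches can resume.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone

from .evaluation import MetricSet, compute_metrics

#: One-dimensional tuning ranges conventionally explored for this model.
TUNING_SWEEPS: dict[str, tuple] = {
    "dropout": tuple(round(0.1 * i, 1) for i in range(1, 10)),
    "l2": (1e-3, 1e-4, 1e-5, 1e-6),
    "n_maps": (50, 100, 200, 400, 600, 1000),
    "batch_size": (32, 48, 64, 96, 128),
}

#: The 3 x 3 x 4 optimization space searched with the AdaMax updater.
OPTIMIZATION_GRID: dict[str, tuple] = {
    "learning_rate": (1e-5, 1e-3, 1e-1),
    "l2": (1e-5, 1e-3, 1e-1),
    "activation": ("relu", "leaky_relu", "sigmoid", "tanh"),
}


class SearchConfigError(ValueError):
    """An invalid search-space or sweep declaration."""


@dataclass(frozen=True)
class SearchSpace:
    """Named hyperparameter dimensions: finite value lists and/or bounded
    continuous ``(low, high)`` ranges sampled uniformly."""

    dimensions: Mapping[str, Sequence] = field(default_factory=dict)
    continuous: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.dimensions.items():
            if len(values) == 0:
                raise SearchConfigError(f"dimension {name!r} is empty")
        for name, (lo, hi) in self.continuous.items():
            if not lo < hi:
                raise SearchConfigError(
                    f"continuous dimension {name!r} needs low < high"
                )

    @property
    def names(self) -> list[str]:
        return list(self.dimensions) + list(self.continuous)

    @property
    def grid_size(self) -> int:
        if self.continuous:
            raise SearchConfigError(
                "grid search requires finite dimensions; "
                f"{list(self.continuous)} are continuous"
            )
        size = 1
        for values in self.dimensions.values():
            size *= len(values)
        return size


@dataclass(frozen=True)
class TrialResult:
    """One fitted configuration with its selection loss and metrics."""

    assignment: dict
    val_loss: float
    metrics: MetricSet
    wall_time: float
    seed: int


def _run_trial(base_estimator, assignment, data, seed) -> TrialResult:
    X_tr, y_tr, X_va, y_va = data
    model = clone(base_estimator)
    model.set_params(**assignment)
    if hasattr(model, "seed"):
        model.set_params(seed=seed)
    t0 = time.perf_counter()
    model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
    wall = time.perf_counter() - t0
    val_loss = float(model.best_val_loss_)
    metrics = compute_metrics(np.asarray(y_va), model.predict(X_va))
    return TrialResult(
        assignment=dict(assignment),
        val_loss=val_loss,
        metrics=metrics,
        wall_time=wall,
        seed=seed,
    )


def _log_trial(log, trial: TrialResult) -> None:
    if log is None:
        return
    record = {
        "assignment": trial.assignment,
        "val_loss": trial.val_loss,
        "metrics": trial.metrics.as_dict(),
        "wall_time": trial.wall_time,
        "seed": trial.seed,
    }
    with Path(log).open("a", encoding="utf-8") as fh:
        fh.write(json.dumps(record) + "\n")


def _resume_trials(log) -> list[TrialResult]:
    """Trials already present in a JSON-lines log, for seamless resumption."""
    if log is None or not Path(log).exists():
        return []
    out = []
    with Path(log).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                TrialResult(
                    assignment=rec["assignment"],
                    val_loss=rec["val_loss"],
                    metrics=MetricSet(**rec["metrics"]),
                    wall_time=rec["wall_time"],
                    seed=rec["seed"],
                )
            )
    return out


def sweep(
    dimension: str,
    values: Sequence,
    base_estimator,
    data,
    seed: int = 0,
    log_path=None,
) -> list[TrialResult]:
    """One trial per value of a single hyperparameter, others fixed.

    `data` is ``(X_train, y_train, X_val, y_val)``.  Every trial uses the
    same fit seed, so results are invariant to the ordering of `values`.
    Raises :class:`SearchConfigError` for an unknown dimension.
    """
    if dimension not in base_estimator.get_params():
        raise SearchConfigError(
            f"{dimension!r} is not a hyperparameter of "
            f"{type(base_estimator).__name__}"
        )
    results = []
    for value in values:
        trial = _run_trial(base_estimator, {dimension: value}, data, seed)
        _log_trial(log_path, trial)
        results.append(trial)
    return results


def _best(trials: Sequence[TrialResult]) -> TrialResult:
    best = trials[0]
    for t in trials[1:]:
        if t.val_loss < best.val_loss:  # strict: first occurrence wins ties
            best = t
    return best


def grid_search(
    space: SearchSpace,
    data,
    base_estimator,
    seed: int = 0,
    log_path=None,
) -> tuple[TrialResult, list[TrialResult]]:
    """Exhaustive search: one fit per point of the Cartesian product.

    The trial count equals the product of dimension sizes; the best trial
    minimizes validation loss, ties broken by enumeration order (dimensions
    iterate in declaration order, later dimensions fastest).
    """
    space.grid_size  # raises on continuous dimensions
    names = list(space.dimensions)
    trials = _resume_trials(log_path)
    for i, combo in enumerate(
        itertools.product(*(space.dimensions[n] for n in names))
    ):
        if i < len(trials):
            continue
        trial = _run_trial(base_estimator, dict(zip(names, combo)), data, seed)
        _log_trial(log_path, trial)
        trials.append(trial)
    return _best(trials), trials


def random_search(
    space: SearchSpace,
    n_trials: int,
    seed: int,
    data,
    base_estimator,
    log_path=None,
) -> tuple[TrialResult, list[TrialResult]]:
    """Seeded uniform sampling of the space, with replacement.

    Exactly `n_trials` fits; each dimension is drawn independently and
    uniformly (value lists by index, continuous ranges by uniform deviate).
    The same seed reproduces the identical trial sequence.
    """
    if n_trials < 1:
        raise SearchConfigError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_trials):
        a = {}
        for name, values in space.dimensions.items():
            a[name] = values[int(rng.integers(len(values)))]
        for name, (lo, hi) in space.continuous.items():
            a[name] = float(rng.uniform(lo, hi))
        assignments.append(a)
    trials = _resume_trials(log_path)
    for i, assignment in enumerate(assignments):
        if i < len(trials):
            continue
        trial = _run_trial(base_estimator, assignment, data, seed)
        _log_trial(log_path, trial)
        trials.append(trial)
    return _best(trials), trials


def trials_to_csv(trials: Sequence[TrialResult], path) -> Path:
    """Summary CSV: one row per trial with assignment, loss and metrics."""
    path = Path(path)
    names = sorted({k for t in trials for k in t.assignment})
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            ",".join(names)
            + ",val_loss,accuracy,precision,recall,f1,wall_time,seed\n"
        )
        for t in trials:
            row = [str(t.assignment.get(n, "")) for n in names]
            m = t.metrics
            row += [
                f"{t.val_loss:.6g}",
                f"{m.accuracy:.6g}",
                f"{m.precision:.6g}",
                f"{m.recall:.6g}",
                f"{m.f1:.6g}",
                f"{t.wall_time:.3f}",
                str(t.seed),
            ]
            fh.write(",".join(row) + "\n")
    return path
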