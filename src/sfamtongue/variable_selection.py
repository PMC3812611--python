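"""Wrapper electrode (variable) selection.

Fewer input electrodes mean a smaller complement-coded input (2d), a
smaller weight matrix, and often a better-conditioned classifier — on
an embedded target, pruning the array is worth real memory.  This
module provides the classic greedy wrappers (forward, backward,
stepwise) driven by a pluggable evaluator: either a Probabilistic
Neural Network (Parzen-window classifier) or SFAM itself, scored by
group cross-validated recognition rate.

Tie rules are fixed so searches are deterministic: forward additions
prefer the lowest feature index, backward removals the highest, and
the PNN resolves exact score ties toward the lowest class label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .dataset import TongueDataset
from .model_selection import CVPlan, recognition_rate
from .sfam import SFAMParams, fit, fit_scaler

__all__ = [
    "PNNParams",
    "PNNModel",
    "SelectionResult",
    "pnn_fit",
    "pnn_predict",
    "make_pnn_evaluator",
    "make_sfam_evaluator",
    "forward_select",
    "backward_select",
    "stepwise_select",
    "selection_report",
]

#: An evaluator maps (dataset, cv-plan) to a recognition rate in [0, 100].
Evaluator = Callable[[TongueDataset, CVPlan], float]


@dataclass(frozen=True)
class PNNParams:
    """sigma: Gaussian kernel spread on [0, 1]-normalized features."""

    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class PNNModel:
    """Stored normalized training patterns, their labels, and the scaler."""

    patterns: np.ndarray  # (n, d) in [0, 1]
    labels: np.ndarray
    scaler: object
    params: PNNParams


def pnn_fit(data: TongueDataset, params: PNNParams = PNNParams()) -> PNNModel:
    """Memorize the (min-max normalized) training patterns per class."""
    present = set(np.unique(data.y))
    missing = [c for c in range(1, data.n_classes + 1) if c not in present]
    if missing:
        raise ValueError(f"no training samples for class(es) {missing}")
    scaler = fit_scaler(data.X)
    return PNNModel(
        patterns=scaler.transform(data.X), labels=data.y.copy(), scaler=scaler, params=params
    )


def pnn_predict(model: PNNModel, X: np.ndarray) -> np.ndarray:
    """Class-conditional Parzen scores, argmax with ties to the lowest label.

    score_c(x) = mean over class-c patterns of exp(-||x - p||^2 / (2 sigma^2)).
    """
    A = model.scaler.transform(np.atleast_2d(np.asarray(X, dtype=float)))
    classes = np.unique(model.labels)
    scores = np.zeros((A.shape[0], classes.size))
    s2 = 2.0 * model.params.sigma**2
    for k, c in enumerate(classes):
        P = model.patterns[model.labels == c]
        d2 = ((A[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
        scores[:, k] = np.exp(-d2 / s2).mean(axis=1)
    # np.argmax takes the first maximum; classes are ascending, so exact
    # ties resolve to the lowest class label
    return classes[np.argmax(scores, axis=1)]


def _cv_rate(
    data: TongueDataset,
    plan: CVPlan,
    train_predict: Callable[[TongueDataset, TongueDataset], np.ndarray],
) -> float:
    """Pooled recognition rate over all validation folds of the plan."""
    y_true: list[np.ndarray] = []
    y_pred: list[np.ndarray] = []
    all_groups = [g for fold in plan.fold_groups for g in fold]
    for val_groups in plan.fold_groups:
        train = data.subset_groups([g for g in all_groups if g not in val_groups])
        val = data.subset_groups(list(val_groups))
        y_true.append(val.y)
        y_pred.append(train_predict(train, val))
    return recognition_rate(np.concatenate(y_true), np.concatenate(y_pred))


def make_pnn_evaluator(
    params: PNNParams = PNNParams(), mode: str = "cv"
) -> Evaluator:
    """PNN-based subset evaluator.

    ``mode="cv"`` (default) scores by group cross-validation over the
    plan; ``mode="resubstitution"`` trains and scores on the full set.
    The scaler is re-fitted per training subset, so no information
    leaks between folds or feature subsets.
    """
    if mode not in ("cv", "resubstitution"):
        raise ValueError("mode must be 'cv' or 'resubstitution'")

    def evaluate(data: TongueDataset, plan: CVPlan) -> float:
        if mode == "resubstitution":
            model = pnn_fit(data, params)
            return recognition_rate(data.y, pnn_predict(model, data.X))
        return _cv_rate(
            data, plan, lambda tr, va: pnn_predict(pnn_fit(tr, params), va.X)
        )

    return evaluate


def make_sfam_evaluator(params: SFAMParams = SFAMParams()) -> Evaluator:
    """SFAM-based subset evaluator (cross-validated recognition rate)."""

    def evaluate(data: TongueDataset, plan: CVPlan) -> float:
        return _cv_rate(data, plan, lambda tr, va: fit(tr, params).predict_batch(va.X))

    return evaluate


@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected electrode names, their CV rate, and the step trace."""

    selected: tuple[str, ...]
    rate: float
    trace: tuple[tuple[tuple[str, ...], float], ...]

    def to_text(self, method: str = "") -> str:
        head = f"{method}\t" if method else ""
        return f"{head}{'/'.join(self.selected)}\t{self.rate:.1f}%"


def _score_subset(
    data: TongueDataset, subset: Sequence[int], evaluator: Evaluator, plan: CVPlan
) -> float:
    return evaluator(data.subset_features(list(subset)), plan)


def forward_select(
    data: TongueDataset,
    evaluator: Evaluator,
    plan: CVPlan,
    target_size: int | None = None,
) -> SelectionResult:
    """Greedy forward addition.

    At each step the feature whose addition maximizes the CV rate joins
    the set (ties -> lowest feature index).  Stops at ``target_size``
    or, when no target is given, as soon as no addition strictly
    improves the rate.
    """
    d = data.n_features
    if target_size is not None and target_size > d:
        raise ValueError(f"target size {target_size} exceeds {d} features")
    selected: list[int] = []
    best_rate = -np.inf
    trace: list[tuple[tuple[str, ...], float]] = []
    while len(selected) < (target_size if target_size is not None else d):
        candidates = [i for i in range(d) if i not in selected]
        if not candidates:
            break
        scores = [_score_subset(data, selected + [i], evaluator, plan) for i in candidates]
        k = int(np.argmax(scores))  # first max -> lowest index
        if target_size is None and scores[k] <= best_rate:
            break
        selected.append(candidates[k])
        best_rate = scores[k]
        trace.append((tuple(data.feature_names[i] for i in selected), best_rate))
    return SelectionResult(
        selected=tuple(data.feature_names[i] for i in selected),
        rate=best_rate if selected else 0.0,
        trace=tuple(trace),
    )


def backward_select(
    data: TongueDataset,
    evaluator: Evaluator,
    plan: CVPlan,
    target_size: int | None = None,
) -> SelectionResult:
    """Greedy backward elimination.

    Starts from all features and repeatedly removes the one whose
    deletion maximizes (or least harms) the CV rate; ties remove the
    highest index.  Stops at ``target_size`` or, without a target, when
    no removal strictly improves; the selected set is never emptied.
    """
    d = data.n_features
    if d < 2:
        raise ValueError("backward selection needs at least 2 features")
    if target_size is not None and target_size >= d:
        raise ValueError(f"target size {target_size} must be below {d}")
    selected = list(range(d))
    best_rate = _score_subset(data, selected, evaluator, plan)
    trace: list[tuple[tuple[str, ...], float]] = [
        (tuple(data.feature_names[i] for i in selected), best_rate)
    ]
    floor = target_size if target_size is not None else 1
    while len(selected) > floor:
        scores = [
            _score_subset(data, [j for j in selected if j != i], evaluator, plan)
            for i in selected
        ]
        # ties -> remove the highest index: scan from the end
        k = len(scores) - 1 - int(np.argmax(scores[::-1]))
        if target_size is None and scores[k] < best_rate:
            break
        best_rate = scores[k]
        del selected[k]
        trace.append((tuple(data.feature_names[i] for i in selected), best_rate))
    return SelectionResult(
        selected=tuple(data.feature_names[i] for i in selected),
        rate=best_rate,
        trace=tuple(trace),
    )


def stepwise_select(
    data: TongueDataset, evaluator: Evaluator, plan: CVPlan
) -> SelectionResult:
    """Alternating forward-add / backward-drop until neither strictly improves."""
    d = data.n_features
    selected: list[int] = []
    best_rate = -np.inf
    trace: list[tuple[tuple[str, ...], float]] = []
    while True:
        improved = False
        candidates = [i for i in range(d) if i not in selected]
        if candidates:
            scores = [
                _score_subset(data, selected + [i], evaluator, plan) for i in candidates
            ]
            k = int(np.argmax(scores))
            if scores[k] > best_rate:
                selected.append(candidates[k])
                best_rate = scores[k]
                trace.append((tuple(data.feature_names[i] for i in selected), best_rate))
                improved = True
        if len(selected) > 1:
            scores = [
                _score_subset(data, [j for j in selected if j != i], evaluator, plan)
                for i in selected
            ]
            k = len(scores) - 1 - int(np.argmax(scores[::-1]))
            if scores[k] > best_rate:
                best_rate = scores[k]
                del selected[k]
                trace.append((tuple(data.feature_names[i] for i in selected), best_rate))
                improved = True
        if not improved:
            break
    return SelectionResult(
        selected=tuple(data.feature_names[i] for i in selected),
        rate=best_rate if selected else 0.0,
        trace=tuple(trace),
    )


def selection_report(results: dict[str, SelectionResult]) -> str:
    """Tab-separated table: method, variables selected, rate."""
    lines = ["Method\tVariables Selected\tRate"]
    lines += [res.to_text(method) for method, res in results.items()]
    return "\n".join(lines) + "\n"
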