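"""Memory-aware model selection for SFAM on replicate-grouped data.

For an embedded target the objective is two-headed: maximize the
recognition rate on held-out replicate groups while minimizing the
mapfield size O (each committed category costs ``2d`` stored weights
plus a label).  This module sweeps a (rho, beta) grid on a fixed
train/validation group split, repeats the sweep over an order-k group
cross-validation plan, and selects the best cell lexicographically:
highest rate, then smallest mapfield, then smallest rho, then smallest
beta (cheaper, less vigilant models win ties).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np

from .dataset import TongueDataset
from .sfam import SFAMParams, fit

__all__ = [
    "GridSpec",
    "GridResult",
    "CVPlan",
    "BestCell",
    "CVResult",
    "recognition_rate",
    "confusion_matrix",
    "make_group_kfold",
    "grid_search",
    "cross_validate_grid",
    "select_best",
]


def recognition_rate(y_true, y_pred) -> float:
    """Percentage of samples whose predicted class equals the true class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and of equal length")
    if y_true.size == 0:
        raise ValueError("cannot score an empty label vector")
    return 100.0 * float(np.mean(y_true == y_pred))


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """M x M count matrix: entry (i, j) = samples of true class i predicted j.

    Labels are 1-based (1..M); row sums equal per-class sample counts.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if v.size and (v.min() < 1 or v.max() > n_classes):
            raise ValueError(f"{name} contains labels outside 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return cm


@dataclass(frozen=True)
class GridSpec:
    """Ascending rho (vigilance) and beta (learning-rate) sweep values."""

    rho_values: tuple[float, ...]
    beta_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals, lo, hi, lo_open in (
            ("rho_values", self.rho_values, 0.0, 1.0, False),
            ("beta_values", self.beta_values, 0.0, 1.0, True),
        ):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly ascending")
            if vals[0] < lo or (lo_open and vals[0] <= lo) or vals[-1] > hi:
                raise ValueError(f"{name} out of bounds")

    @classmethod
    def coarse(cls) -> "GridSpec":
        """Whole-range sweep at 0.1 steps: rho 0.1..0.9, beta 0.1..1.0 (9 x 10)."""
        return cls(
            rho_values=tuple(np.round(np.arange(1, 10) * 0.1, 2)),
            beta_values=tuple(np.round(np.arange(1, 11) * 0.1, 2)),
        )

    @classmethod
    def fine(
        cls,
        rho_range: tuple[float, float] = (0.1, 0.3),
        beta_range: tuple[float, float] = (0.7, 0.8),
        step: float = 0.05,
    ) -> "GridSpec":
        """Refinement sweep at 0.05 steps (default rho 0.1-0.3 x beta 0.7-0.8, 5 x 3)."""

        def _axis(lo: float, hi: float) -> tuple[float, ...]:
            n = int(round((hi - lo) / step)) + 1
            return tuple(np.round(lo + step * np.arange(n), 4))

        return cls(rho_values=_axis(*rho_range), beta_values=_axis(*beta_range))


@dataclass(frozen=True)
class GridResult:
    """Recognition-rate (%) and mapfield-size matrices over a (rho, beta) grid."""

    rates: np.ndarray  # |rho| x |beta|, percent
    mapfields: np.ndarray  # |rho| x |beta|, category counts
    spec: GridSpec
    description: str = ""

    def __post_init__(self) -> None:
        shape = (len(self.spec.rho_values), len(self.spec.beta_values))
        if self.rates.shape != shape or self.mapfields.shape != shape:
            raise ValueError("matrix shapes must match the grid spec")

    def _frame(self, M: np.ndarray):
        import pandas as pd

        return pd.DataFrame(
            M,
            index=[f"{r:g}" for r in self.spec.rho_values],
            columns=[f"{b:g}" for b in self.spec.beta_values],
        )

    def to_csv(self, rates_path, mapfields_path) -> None:
        """Two CSV matrices with rho row labels and beta column labels."""
        self._frame(np.round(self.rates, 1)).to_csv(rates_path, index_label="rho/beta")
        self._frame(self.mapfields).to_csv(mapfields_path, index_label="rho/beta")

    def to_text(self) -> str:
        """Plain-text report: the two matrices side by side with the split description."""
        buf = _io.StringIO()
        if self.description:
            buf.write(f"# {self.description}\n")
        buf.write("Recognition rate (%)\n")
        buf.write(self._frame(np.round(self.rates, 1)).to_string())
        buf.write("\n\nMapfield (1xO)\n")
        buf.write(self._frame(self.mapfields).to_string())
        buf.write("\n")
        return buf.getvalue()


@dataclass(frozen=True)
class BestCell:
    rho: float
    beta: float
    rate: float
    mapfield: int
    fold: int | None = None


@dataclass(frozen=True)
class CVPlan:
    """Group-disjoint fold assignment: ``fold_groups[f]`` are fold f's validation groups."""

    k: int
    fold_groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fold in self.fold_groups:
            if seen.intersection(fold):
                raise ValueError("folds must be group-disjoint")
            seen.update(fold)
        if len(self.fold_groups) != self.k:
            raise ValueError("fold count must equal k")


def make_group_kfold(groups, k: int) -> CVPlan:
    """Assign replicate groups to k folds as contiguous blocks.

    Groups are taken in first-appearance order and must divide evenly
    into k blocks; e.g. M1-M8 with k=4 gives validation folds
    {M1,M2}, {M3,M4}, {M5,M6}, {M7,M8}.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    order: list[str] = []
    for g in np.asarray(groups):
        g = str(g)
        if g not in order:
            order.append(g)
    if len(order) % k:
        raise ValueError(f"{len(order)} groups cannot be split into {k} equal folds")
    per = len(order) // k
    folds = tuple(tuple(order[f * per : (f + 1) * per]) for f in range(k))
    return CVPlan(k=k, fold_groups=folds)


def grid_search(
    data: TongueDataset,
    spec: GridSpec,
    train_groups: list[str],
    val_groups: list[str],
    params_base: SFAMParams = SFAMParams(),
) -> GridResult:
    """Sweep the grid on one fixed train/validation group split.

    For every (rho, beta) cell, an SFAM network is trained from scratch
    on the training groups and scored on the validation groups; the
    mapfield size of the trained network is recorded alongside.  Pure
    function of its inputs: repeated calls are bit-identical.
    """
    if set(train_groups) & set(val_groups):
        raise ValueError("train and validation groups must be disjoint")
    train = data.subset_groups(list(train_groups))
    val = data.subset_groups(list(val_groups))
    rates = np.zeros((len(spec.rho_values), len(spec.beta_values)))
    mapfields = np.zeros_like(rates, dtype=int)
    from dataclasses import replace as _replace

    for i, rho in enumerate(spec.rho_values):
        for j, beta in enumerate(spec.beta_values):
            model = fit(train, _replace(params_base, rho=rho, beta=beta))
            rates[i, j] = recognition_rate(val.y, model.predict_batch(val.X))
            mapfields[i, j] = model.mapfield_size
    desc = f"train={','.join(train_groups)} validation={','.join(val_groups)}"
    return GridResult(rates=rates, mapfields=mapfields, spec=spec, description=desc)


def select_best(result: GridResult) -> BestCell:
    """Best grid cell: max rate, then min mapfield, then min rho, then min beta."""
    best: tuple | None = None
    for i, rho in enumerate(result.spec.rho_values):
        for j, beta in enumerate(result.spec.beta_values):
            key = (-result.rates[i, j], result.mapfields[i, j], rho, beta)
            if best is None or key < best[0]:
                best = (key, i, j)
    assert best is not None
    _, i, j = best
    return BestCell(
        rho=float(result.spec.rho_values[i]),
        beta=float(result.spec.beta_values[j]),
        rate=float(result.rates[i, j]),
        mapfield=int(result.mapfields[i, j]),
    )


@dataclass(frozen=True)
class CVResult:
    """Per-fold grid results plus the overall best (fold, rho, beta) summary."""

    folds: tuple[GridResult, ...]
    plan: CVPlan
    best: BestCell


def cross_validate_grid(
    data: TongueDataset,
    spec: GridSpec,
    plan: CVPlan,
    params_base: SFAMParams = SFAMParams(),
) -> CVResult:
    """Run the grid sweep once per CV fold and summarize the best cell.

    Fold f validates on ``plan.fold_groups[f]`` and trains on every
    other group in the plan.  The summary is the cell, over all folds,
    with the best recognition rate and the smallest mapfield (ties as
    in :func:`select_best`, then lowest fold index).
    """
    all_groups = [g for fold in plan.fold_groups for g in fold]
    results = []
    best: BestCell | None = None
    for f, val in enumerate(plan.fold_groups):
        train = [g for g in all_groups if g not in val]
        res = grid_search(data, spec, train, list(val), params_base)
        results.append(res)
        cell = select_best(res)
        cand = BestCell(cell.rho, cell.beta, cell.rate, cell.mapfield, fold=f)
        if best is None or (
            (-cand.rate, cand.mapfield, cand.rho, cand.beta)
            < (-best.rate, best.mapfield, best.rho, best.beta)
        ):
            best = cand
    assert best is not None
    return CVResult(folds=tuple(results), plan=plan, best=best)
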