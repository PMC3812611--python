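"""Tabular container for electronic-tongue measurement campaigns.

A :class:`TongueDataset` holds one row per assay: the steady-state
potential (mV) of each working electrode, a class label (e.g. floral
origin, coded ``1..M``), and a replicate-group identifier (``M1``,
``M2``, ...).  Replicate groups are the unit of cross-validation:
assays from the same group share sample handling and must never be
split between training and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TongueDataset"]


@dataclass
class TongueDataset:
    """Sample x electrode matrix with class labels and replicate groups.

    Parameters
    ----------
    X : (n, d) float array
        Raw electrode potentials in mV.
    y : (n,) int array
        Class labels in ``1..M``.
    groups : (n,) array of str
        Replicate-group identifier per row (``"M1"`` style).
    feature_names : tuple of str
        One name per electrode column.
    treatment : (n,) int array, optional
        Secondary label (physical treatment, ``1..T``); carried through
        subsetting but ignored by classifiers unless used as ``y``.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: tuple[str, ...] = field(default=())
    treatment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D sample x electrode matrix")
        n = self.X.shape[0]
        if n == 0:
            raise ValueError("dataset must contain at least one sample")
        if self.y.shape != (n,) or self.groups.shape != (n,):
            raise ValueError(
                f"inconsistent lengths: X has {n} rows, "
                f"y has {self.y.shape[0]}, groups has {self.groups.shape[0]}"
            )
        if not self.feature_names:
            self.feature_names = tuple(f"E{i + 1}" for i in range(self.X.shape[1]))
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names must match the number of columns")
        if self.y.min() < 1:
            raise ValueError("class labels must be positive integers (1..M)")
        if self.treatment is not None:
            self.treatment = np.asarray(self.treatment, dtype=int)
            if self.treatment.shape != (n,):
                raise ValueError("treatment length must match the number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max())

    @property
    def group_order(self) -> list[str]:
        """Distinct groups in first-appearance (row) order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(str(g), None)
        return list(seen)

    def subset_rows(self, mask: np.ndarray) -> "TongueDataset":
        treat = None if self.treatment is None else self.treatment[mask]
        return replace(
            self, X=self.X[mask], y=self.y[mask], groups=self.groups[mask], treatment=treat
        )

    def subset_groups(self, names: list[str]) -> "TongueDataset":
        """Rows belonging to the given replicate groups, in original row order."""
        known = set(self.group_order)
        unknown = [g for g in names if g not in known]
        if unknown:
            raise KeyError(f"unknown replicate groups: {unknown}; available: {sorted(known)}")
        mask = np.isin(self.groups.astype(str), list(names))
        return self.subset_rows(mask)

    def subset_features(self, names: list[str] | list[int]) -> "TongueDataset":
        """Column subset by electrode name or index (order as given)."""
        idx: list[int] = []
        for name in names:
            if isinstance(name, (int, np.integer)):
                idx.append(int(name))
            else:
                try:
                    idx.append(self.feature_names.index(name))
                except ValueError:
                    raise KeyError(
                        f"unknown electrode {name!r}; valid names: {list(self.feature_names)}"
                    ) from None
        return replace(
            self,
            X=self.X[:, idx],
            feature_names=tuple(self.feature_names[i] for i in idx),
        )
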