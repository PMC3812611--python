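"""Simplified Fuzzy ARTMAP (SFAM) classifier.

SFAM is a supervised, incrementally learning variant of Fuzzy ARTMAP.
It keeps a pool of *category* prototype vectors (the top-down weight
rows ``W_j``), each tagged with a class label through the *mapfield*
(output category layer).  Inputs are min-max normalized and complement
coded (``a -> [a, 1 - a]``), which fixes their L1 norm at ``d`` and
prevents category proliferation from weight erosion.

Training presents each pattern to a resonance search:

* activation (choice) of category ``j``: ``T_j = |I ^ w_j| / (alpha + |w_j|)``
  with ``^`` the componentwise minimum and ``|.|`` the L1 norm;
* the winner must pass the vigilance test ``|I ^ w_j| / |I| >= rho``;
* on a label mismatch, *match tracking* raises the working vigilance just
  above the offending category's match value, disqualifying it and every
  equally general competitor for the rest of this pattern's search;
* if no committed category resonates with the right label, a new category
  is created with ``w = I``.

A resonating category learns ``w' = beta * (I ^ w) + (1 - beta) * w``;
``beta = 1`` is *fast learning* (weights snap to ``I ^ w`` in one step),
and weights are componentwise non-increasing over the life of a model.

The test (non-supervised) phase is a pure argmax of the choice function
over committed categories; this is the routine a deployment target has
to reproduce from the exported weight matrix, mapfield and min/max
vectors alone (see :mod:`sfamtongue.deploy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import TongueDataset

__all__ = [
    "SFAMParams",
    "FeatureScaler",
    "SFAMModel",
    "fit_scaler",
    "complement_code",
    "choice",
    "match",
    "learn",
    "fit",
]


@dataclass(frozen=True)
class SFAMParams:
    """Hyperparameters of the SFAM network.

    beta : learning rate in (0, 1]; 1 is fast learning.
    rho : baseline vigilance in [0, 1]; higher values grow more, narrower
        categories (a larger mapfield).
    alpha : choice parameter > 0; small values bias the winner search
        toward more specific (smaller-norm) categories.
    epsilon : match-tracking increment > 0; how far above the offending
        match the working vigilance is raised on a label mismatch.
    max_epochs : epoch cap; training also stops as soon as a full epoch
        changes no weight.
    max_categories : optional cap on committed categories (None = unbounded).
    shuffle, seed : optional seeded per-epoch shuffling of the
        presentation order; off by default so runs are reproducible
        without a seed.
    """

    beta: float = 1.0
    rho: float = 0.5
    alpha: float = 0.001
    epsilon: float = 0.001
    max_epochs: int = 100
    max_categories: int | None = None
    shuffle: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.alpha <= 0.0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.epsilon <= 0.0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be a positive integer")
        if self.max_categories is not None and self.max_categories < 1:
            raise ValueError("max_categories must be positive or None")


@dataclass(frozen=True)
class FeatureScaler:
    """Per-electrode min/max (mV) used for input normalization.

    These two vectors are part of the deployable state: the device
    normalizes incoming raw potentials with exactly these extrema, so
    the scaler is always fitted on training data only and test inputs
    are clipped into [0, 1].
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=float))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=float))
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ValueError("mins and maxs must be 1-D vectors of equal length")
        if np.any(self.mins > self.maxs):
            raise ValueError("scaler requires mins[i] <= maxs[i] for all i")

    @property
    def d(self) -> int:
        return self.mins.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Normalize raw potentials to [0, 1], clipping out-of-range values.

        A constant electrode (min == max) maps to 0.
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.d:
            raise ValueError(f"expected {self.d} features, got {x.shape[-1]}")
        span = self.maxs - self.mins
        safe = np.where(span > 0.0, span, 1.0)
        a = (x - self.mins) / safe
        a = np.where(span > 0.0, a, 0.0)
        return np.clip(a, 0.0, 1.0)


def fit_scaler(X: np.ndarray) -> FeatureScaler:
    """Columnwise min/max of a raw sample matrix.

    Rejects empty matrices and non-finite entries (naming the offending
    column), since a corrupt extremum would be burned into the device.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("fit_scaler requires a non-empty 2-D sample matrix")
    bad = np.where(~np.isfinite(X).all(axis=0))[0]
    if bad.size:
        raise ValueError(f"non-finite values in column(s) {bad.tolist()}")
    return FeatureScaler(mins=X.min(axis=0), maxs=X.max(axis=0))


def complement_code(a: np.ndarray) -> np.ndarray:
    """Append ``1 - a`` to a normalized vector: ``[a, 1 - a]``.

    The result has length ``2d`` and L1 norm exactly ``d``.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("complement_code requires a non-empty 1-D vector")
    if np.any(a < 0.0) or np.any(a > 1.0):
        raise ValueError("complement coding requires components in [0, 1]")
    return np.concatenate([a, 1.0 - a])


def _check_pair(I: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    I = np.asarray(I, dtype=float)
    w = np.asarray(w, dtype=float)
    if I.shape != w.shape:
        raise ValueError(f"length mismatch: input {I.shape} vs weights {w.shape}")
    return I, w


def choice(I: np.ndarray, w: np.ndarray, alpha: float) -> float:
    """Category activation ``T = |I ^ w| / (alpha + |w|)``."""
    I, w = _check_pair(I, w)
    return float(np.minimum(I, w).sum() / (alpha + w.sum()))


def match(I: np.ndarray, w: np.ndarray) -> float:
    """Vigilance match ``|I ^ w| / |I|`` (``|I| = d`` for complement-coded input)."""
    I, w = _check_pair(I, w)
    return float(np.minimum(I, w).sum() / I.sum())


def learn(w: np.ndarray, I: np.ndarray, beta: float) -> np.ndarray:
    """Weight update ``w' = beta * (I ^ w) + (1 - beta) * w``; never grows."""
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    I, w = _check_pair(I, w)
    return beta * np.minimum(I, w) + (1.0 - beta) * w


class CapacityError(RuntimeError):
    """Raised when training would exceed ``max_categories``."""


@dataclass
class SFAMModel:
    """A trained (or trainable) SFAM network: the entire deployable state."""

    d: int
    params: SFAMParams
    scaler: FeatureScaler
    n_classes: int
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    mapfield: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.empty((0, 2 * self.d), dtype=float)
        if self.mapfield is None:
            self.mapfield = np.empty((0,), dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.mapfield = np.asarray(self.mapfield, dtype=int)
        if self.weights.shape != (self.mapfield.shape[0], 2 * self.d):
            raise ValueError("weights must be O x 2d with O == len(mapfield)")

    @property
    def mapfield_size(self) -> int:
        """Number of committed categories O (the memory-cost metric)."""
        return int(self.mapfield.shape[0])

    # -- training ---------------------------------------------------------

    def train_pattern(self, I: np.ndarray, label: int) -> bool:
        """Present one complement-coded pattern; returns True if weights changed.

        Runs the resonance search with match tracking at the model's
        baseline vigilance; the raised working vigilance is local to
        this call.
        """
        I = np.asarray(I, dtype=float)
        if I.shape != (2 * self.d,):
            raise ValueError(f"expected complement-coded length {2 * self.d}, got {I.shape}")
        p = self.params
        if self.mapfield_size:
            overlap = np.minimum(I[None, :], self.weights).sum(axis=1)
            T = overlap / (p.alpha + self.weights.sum(axis=1))
            m = overlap / I.sum()
            rho_working = p.rho
            # descending activation, ties toward the oldest category
            for j in np.argsort(-T, kind="stable"):
                if m[j] < rho_working:
                    continue
                if self.mapfield[j] == int(label):
                    new_w = learn(self.weights[j], I, p.beta)
                    changed = not np.array_equal(new_w, self.weights[j])
                    self.weights[j] = new_w
                    return changed
                rho_working = m[j] + p.epsilon  # match tracking
        if p.max_categories is not None and self.mapfield_size >= p.max_categories:
            raise CapacityError(
                f"cannot commit a new category: max_categories={p.max_categories} reached"
            )
        self.weights = np.vstack([self.weights, I[None, :]])
        self.mapfield = np.append(self.mapfield, int(label))
        return True

    # -- inference --------------------------------------------------------

    def _code(self, x: np.ndarray) -> np.ndarray:
        return complement_code(self.scaler.transform(np.asarray(x, dtype=float)))

    def predict(self, x: np.ndarray, reject_below: float | None = None) -> int:
        """Classify one raw feature vector (mV).

        Normalize, complement-code, and return the mapfield label of the
        category with the highest choice activation (ties -> lowest
        index).  No vigilance test is applied by default; with
        ``reject_below=rho`` set, inputs whose winning match falls below
        ``rho`` return 0 ("unknown").
        """
        if self.mapfield_size == 0:
            raise ValueError("model has no committed categories; train it first")
        I = self._code(x)
        overlap = np.minimum(I[None, :], self.weights).sum(axis=1)
        T = overlap / (self.params.alpha + self.weights.sum(axis=1))
        j = int(np.argmax(T))
        if reject_below is not None and overlap[j] / I.sum() < reject_below:
            return 0
        return int(self.mapfield[j])

    def predict_batch(self, X: np.ndarray, reject_below: float | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.predict(x, reject_below) for x in X], dtype=int)


def fit(data: TongueDataset, params: SFAMParams) -> SFAMModel:
    """Supervised (training) phase on a dataset, in row order.

    The scaler is fitted on the training data only.  Patterns are
    presented in dataset row order each epoch (or in a seeded shuffled
    order when ``params.shuffle``); training stops when an epoch changes
    no weight or after ``max_epochs``.
    """
    scaler = fit_scaler(data.X)
    model = SFAMModel(
        d=data.n_features, params=params, scaler=scaler, n_classes=data.n_classes
    )
    coded = np.stack([complement_code(a) for a in scaler.transform(data.X)])
    labels = data.y
    rng = np.random.default_rng(params.seed) if params.shuffle else None
    for _ in range(params.max_epochs):
        order = rng.permutation(len(labels)) if rng is not None else range(len(labels))
        epoch_changed = False
        for i in order:
            if model.train_pattern(coded[i], int(labels[i])):
                epoch_changed = True
        if not epoch_changed:
            break
    return model
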