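"""Synthetic potentiometric electronic-tongue data.

Emulates a honey-authentication measurement campaign: an array of
metallic working electrodes (Au, Ag, Cu, AgO2, CuO2, AgCl, Ag2CO3)
immersed in samples spanning four floral origins x three physical
treatments x four repetitions = 48 assays.  Each assay is a 5-minute
potential time series sampled every 10 s that relaxes exponentially to
an electrochemical equilibrium; the steady-state value is the mean of
the last ten readings.  Rows are coded into consecutive replicate
groups M1, M2, ... of four samples cycling through the floral classes
1-4, with the physical treatment cycling 1-3 across rows.

The generated world is deliberately simple: per-class per-electrode
equilibrium means, additive per-treatment per-electrode offsets,
i.i.d. Gaussian reading noise, single-exponential stabilization.  It
does not model drift, fouling or temperature dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import TongueDataset

__all__ = [
    "ELECTRODE_NAMES",
    "TongueConfig",
    "simulate_assay",
    "steady_state_value",
    "generate_dataset",
    "split_train_test",
    "separable_config",
    "selection_benchmark_config",
]

#: Default electrode array: three pure metals plus four electrolytically
#: treated surfaces, mirroring a seven-electrode potentiometric tongue.
ELECTRODE_NAMES = ("Au", "Ag", "Cu", "AgO2", "CuO2", "AgCl", "Ag2CO3")


@dataclass(frozen=True)
class TongueConfig:
    """Stated world of the generator.

    class_mean_matrix : (n_classes, n_electrodes) equilibrium potentials
        in mV, or None for seeded uniform draws in [-400, 400] mV.
    treatment_offset_matrix : (n_treatments, n_electrodes) additive
        offsets in mV, or None for seeded Normal(0, treatment_offset_scale)
        draws.
    noise_sd : Gaussian noise per 10-s reading, mV.  Averaging the last
        ten readings reduces it by sqrt(10).
    stabilization_tau_s : time constant of the exponential approach to
        equilibrium; 30 s leaves a relative residual of e^-10 after the
        5-minute assay.
    """

    n_electrodes: int = 7
    n_classes: int = 4
    n_treatments: int = 3
    repetitions: int = 4
    class_mean_matrix: np.ndarray | None = None
    treatment_offset_matrix: np.ndarray | None = None
    treatment_offset_scale: float = 20.0
    noise_sd: float = 5.0
    assay_duration_s: int = 300
    sampling_period_s: int = 10
    stabilization_tau_s: float = 30.0
    start_potential_mv: float = 0.0
    seed: int = 0
    electrode_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("n_electrodes", "n_classes", "n_treatments", "repetitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.assay_duration_s % self.sampling_period_s:
            raise ValueError("sampling period must divide the assay duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.stabilization_tau_s <= 0:
            raise ValueError("stabilization time constant must be positive")
        if not self.electrode_names:
            names = (
                ELECTRODE_NAMES[: self.n_electrodes]
                if self.n_electrodes <= len(ELECTRODE_NAMES)
                else ELECTRODE_NAMES
                + tuple(f"E{i + 1}" for i in range(len(ELECTRODE_NAMES), self.n_electrodes))
            )
            object.__setattr__(self, "electrode_names", names)
        if len(self.electrode_names) != self.n_electrodes:
            raise ValueError("electrode_names must match n_electrodes")
        for attr, rows in (
            ("class_mean_matrix", self.n_classes),
            ("treatment_offset_matrix", self.n_treatments),
        ):
            m = getattr(self, attr)
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.shape != (rows, self.n_electrodes):
                    raise ValueError(f"{attr} must have shape ({rows}, {self.n_electrodes})")
                object.__setattr__(self, attr, m)

    @property
    def n_readings(self) -> int:
        return self.assay_duration_s // self.sampling_period_s

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.n_treatments * self.repetitions


def simulate_assay(
    target_mv: float, config: TongueConfig, rng: np.random.Generator
) -> np.ndarray:
    """One electrode's potential time series for one assay.

    reading(t) = target * (1 - exp(-t/tau)) + start * exp(-t/tau) + N(0, noise_sd),
    sampled at t = period, 2*period, ..., duration (30 readings at the
    defaults).
    """
    t = config.sampling_period_s * np.arange(1, config.n_readings + 1, dtype=float)
    decay = np.exp(-t / config.stabilization_tau_s)
    trace = target_mv * (1.0 - decay) + config.start_potential_mv * decay
    if config.noise_sd > 0:
        trace = trace + rng.normal(0.0, config.noise_sd, size=trace.shape)
    return trace


def steady_state_value(trace: np.ndarray, n_last: int = 10) -> float:
    """Mean of the final ``n_last`` readings (noise reduction by averaging)."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < n_last:
        raise ValueError(f"trace must be 1-D with at least {n_last} readings")
    return float(trace[-n_last:].mean())


def _draw_design(config: TongueConfig, rng: np.random.Generator):
    means = config.class_mean_matrix
    if means is None:
        means = rng.uniform(-400.0, 400.0, size=(config.n_classes, config.n_electrodes))
    offsets = config.treatment_offset_matrix
    if offsets is None:
        offsets = rng.normal(
            0.0, config.treatment_offset_scale, size=(config.n_treatments, config.n_electrodes)
        )
    return means, offsets


def generate_dataset(config: TongueConfig = TongueConfig()) -> TongueDataset:
    """Full measurement campaign as a :class:`TongueDataset`.

    Row s carries floral class ``(s mod n_classes) + 1`` and treatment
    ``(s mod n_treatments) + 1`` and belongs to replicate group
    ``M(s // n_classes + 1)``; at the defaults this reproduces the
    48-row, 12-group coding where each group holds one sample per
    floral class and each (class, treatment) pair appears exactly
    ``repetitions`` times.  Each cell is an assay simulation followed
    by last-ten-reading averaging.  Fully deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    means, offsets = _draw_design(config, rng)
    n = config.n_samples
    X = np.zeros((n, config.n_electrodes))
    y = np.zeros(n, dtype=int)
    treatment = np.zeros(n, dtype=int)
    groups = np.empty(n, dtype=object)
    for s in range(n):
        c = s % config.n_classes
        t = s % config.n_treatments
        y[s] = c + 1
        treatment[s] = t + 1
        groups[s] = f"M{s // config.n_classes + 1}"
        for e in range(config.n_electrodes):
            trace = simulate_assay(means[c, e] + offsets[t, e], config, rng)
            X[s, e] = steady_state_value(trace)
    return TongueDataset(
        X=X,
        y=y,
        groups=groups.astype(str),
        feature_names=config.electrode_names,
        treatment=treatment,
    )


def split_train_test(
    data: TongueDataset,
    train_groups: list[str] | None = None,
    test_groups: list[str] | None = None,
) -> tuple[TongueDataset, TongueDataset]:
    """Row-preserving partition by replicate group.

    Defaults to the first two thirds of the groups for training and the
    rest for testing (M1-M8 / M9-M12 on the default campaign, i.e.
    32 training and 16 test assays).
    """
    order = data.group_order
    if train_groups is None and test_groups is None:
        cut = 2 * len(order) // 3
        train_groups, test_groups = order[:cut], order[cut:]
    if not train_groups or not test_groups:
        raise ValueError("both train and test group lists must be non-empty")
    overlap = set(train_groups) & set(test_groups)
    if overlap:
        raise ValueError(f"train/test groups overlap: {sorted(overlap)}")
    return data.subset_groups(list(train_groups)), data.subset_groups(list(test_groups))


def separable_config(seed: int = 0) -> TongueConfig:
    """Zero-noise regime with well-separated random class means.

    Class means are drawn uniformly in [-400, 400] mV per electrode, so
    classes are far apart relative to the 20 mV treatment offsets; any
    reasonable classifier reaches 100% and SFAM can cover each class
    with a single category at suitable (rho, beta).
    """
    return TongueConfig(noise_sd=0.0, seed=seed)


def selection_benchmark_config(noise_sd: float = 0.0, seed: int = 0) -> TongueConfig:
    """Four informative + three dead electrodes, each informative one necessary.

    The mean/offset geometry is constructed so that for each informative
    electrode (Au, Ag, Cu, CuO2) there is a pair of clusters from
    *different* floral classes and *different* treatments that coincide
    everywhere except on that electrode (where they differ by 200 mV).
    Dropping any one of the four therefore merges two clusters of
    different classes and caps the recognition rate below 100%, while
    the full quartet separates all twelve clusters.  AgO2, AgCl and
    Ag2CO3 carry no class or treatment signal at all.

    This is the stated world for wrapper-selection benchmarks: a greedy
    forward/stepwise search must pick exactly the four informative
    electrodes to reach 100%.
    """
    means = np.zeros((4, 7))
    offsets = np.zeros((3, 7))
    info = [0, 1, 2, 4]  # Au, Ag, Cu, CuO2
    means[np.ix_([0, 1, 2, 3], info)] = [
        [0.0, 0.0, 0.0, 0.0],
        [-80.0, 50.0, -60.0, -160.0],
        [360.0, -300.0, -80.0, 120.0],
        [80.0, -250.0, 60.0, -40.0],
    ]
    offsets[np.ix_([1, 2], info)] = [
        [80.0, -50.0, 60.0, -40.0],
        [-360.0, 300.0, -120.0, -120.0],
    ]
    return TongueConfig(
        class_mean_matrix=means,
        treatment_offset_matrix=offsets,
        noise_sd=noise_sd,
        seed=seed,
    )
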