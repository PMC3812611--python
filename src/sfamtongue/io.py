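"""Dataset CSV round-trip and generator-config files.

CSV layout: optional ``#``-prefixed provenance comments, then a header
row ``group,floral_class,treatment_class,<electrode...>`` and one row
per assay.  Numeric round-trips are lossless (full ``repr`` precision)
and row order is preserved.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .dataset import TongueDataset
from .synthetic import TongueConfig

__all__ = ["read_dataset", "write_dataset", "save_config", "load_config"]

_LABEL_COLS = ("group", "floral_class", "treatment_class")


def write_dataset(data: TongueDataset, path, seed: int | None = None) -> None:
    """Write a dataset CSV; a seed, when given, is recorded in a comment."""
    frame = pd.DataFrame(data.X, columns=list(data.feature_names))
    frame.insert(0, "treatment_class", data.treatment if data.treatment is not None else 0)
    frame.insert(0, "floral_class", data.y)
    frame.insert(0, "group", data.groups)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)


def read_dataset(path, electrodes: list[str] | None = None) -> TongueDataset:
    """Read a dataset CSV, optionally restricted to named electrode columns."""
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _LABEL_COLS[:2] if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset CSV is missing required column(s): {missing}")
    feature_cols = [c for c in frame.columns if c not in _LABEL_COLS]
    if electrodes is not None:
        unknown = [e for e in electrodes if e not in feature_cols]
        if unknown:
            raise KeyError(f"unknown electrode(s) {unknown}; valid names: {feature_cols}")
        feature_cols = list(electrodes)
    X = frame[feature_cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-numeric or non-finite electrode cell(s) in dataset CSV")
    treatment = (
        frame["treatment_class"].to_numpy(dtype=int)
        if "treatment_class" in frame.columns
        else None
    )
    return TongueDataset(
        X=X,
        y=frame["floral_class"].to_numpy(dtype=int),
        groups=frame["group"].to_numpy(dtype=str),
        feature_names=tuple(feature_cols),
        treatment=treatment,
    )


def save_config(config: TongueConfig, path) -> None:
    """Write a generator config as YAML (arrays become nested lists)."""
    payload = asdict(config)
    for key in ("class_mean_matrix", "treatment_offset_matrix"):
        if payload[key] is not None:
            payload[key] = np.asarray(payload[key]).tolist()
    payload["electrode_names"] = list(config.electrode_names)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> TongueConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["electrode_names"] = tuple(payload.get("electrode_names") or ())
    for key in ("class_mean_matrix", "treatment_offset_matrix"):
        if payload.get(key) is not None:
            payload[key] = np.asarray(payload[key], dtype=float)
    return TongueConfig(**payload)
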