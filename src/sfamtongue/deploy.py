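"""Export of the deployable SFAM state and a standalone inference routine.

Three artifacts fully determine the test (non-supervised) phase and are
what gets programmed into a microcontroller: the weight matrix (O x 2d),
the mapfield (O class labels), and the per-electrode min/max vectors
used for input normalization.  This module serializes them to either a
compile-checkable C header or a documented portable text format, reports
the memory footprint, and re-implements inference from the bundle alone
so export/import parity can be proven against the source model.

Values are rendered single-precision (decimal representations that
round-trip through a 4-byte float), matching a C-float firmware; labels
are one byte.  Weight rows are flattened row-major and the min/max
vectors are interleaved (min0, max0, min1, max1, ...), with fixed array
names, so emitted headers are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sfam import FeatureScaler, SFAMModel, SFAMParams

__all__ = [
    "ExportBundle",
    "FootprintReport",
    "export_model",
    "import_model",
    "memory_footprint",
    "standalone_predict",
]


def _f32(v: float) -> str:
    """Shortest decimal string that round-trips through float32."""
    return np.format_float_positional(np.float32(v), unique=True, trim="0")


@dataclass(frozen=True)
class ExportBundle:
    """Everything the device needs: shapes, weights, mapfield, min/max."""

    d: int
    O: int
    n_classes: int
    weights: np.ndarray  # (O, 2d), stored at float32 precision
    mapfield: np.ndarray  # (O,) labels in 1..n_classes
    mins: np.ndarray  # (d,)
    maxs: np.ndarray  # (d,)
    value_width_bytes: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=np.float32))
        object.__setattr__(self, "mapfield", np.asarray(self.mapfield, dtype=int))
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=np.float32))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=np.float32))
        if self.weights.shape != (self.O, 2 * self.d):
            raise ValueError("weights must have shape (O, 2d)")
        if self.mapfield.shape != (self.O,):
            raise ValueError("mapfield must have length O")
        if self.mins.shape != (self.d,) or self.maxs.shape != (self.d,):
            raise ValueError("min/max vectors must have length d")

    # -- serialization ----------------------------------------------------

    def to_portable_text(self) -> str:
        """Line format: header ``SFAM d O M``, MIN/MAX lines, one W line per
        category, and the MAP line of labels."""
        lines = [f"SFAM {self.d} {self.O} {self.n_classes}"]
        lines.append("MIN " + " ".join(_f32(v) for v in self.mins))
        lines.append("MAX " + " ".join(_f32(v) for v in self.maxs))
        for row in self.weights:
            lines.append("W " + " ".join(_f32(v) for v in row))
        lines.append("MAP " + " ".join(str(int(v)) for v in self.mapfield))
        return "\n".join(lines) + "\n"

    def to_c_header(self) -> str:
        """Constant arrays for a C-float firmware build."""
        w_flat = ", ".join(_f32(v) + "f" for v in self.weights.ravel())
        minmax = ", ".join(
            _f32(v) + "f" for pair in zip(self.mins, self.maxs) for v in pair
        )
        mapf = ", ".join(str(int(v)) for v in self.mapfield)
        return (
            "/* SFAM deployable parameters: weight matrix, mapfield, input min/max */\n"
            "#ifndef SFAM_PARAMS_H\n"
            "#define SFAM_PARAMS_H\n\n"
            f"#define SFAM_D {self.d}\n"
            f"#define SFAM_O {self.O}\n"
            f"#define SFAM_M {self.n_classes}\n\n"
            f"static const float sfam_weights[{self.O} * 2 * {self.d}] = {{\n"
            f"    {w_flat}\n}};\n\n"
            f"static const unsigned char sfam_mapfield[{self.O}] = {{{mapf}}};\n\n"
            "/* interleaved per-electrode extrema: min0, max0, min1, max1, ... */\n"
            f"static const float sfam_minmax[2 * {self.d}] = {{\n"
            f"    {minmax}\n}};\n\n"
            "#endif /* SFAM_PARAMS_H */\n"
        )


def export_model(model: SFAMModel) -> ExportBundle:
    """Snapshot a trained model's deployable state (values at float32)."""
    if model.mapfield_size == 0:
        raise ValueError("cannot export an untrained model (no committed categories)")
    return ExportBundle(
        d=model.d,
        O=model.mapfield_size,
        n_classes=model.n_classes,
        weights=model.weights,
        mapfield=model.mapfield,
        mins=model.scaler.mins,
        maxs=model.scaler.maxs,
    )


def import_model(text: str) -> SFAMModel:
    """Rebuild an inference-only model from the portable text format."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    try:
        tag, d, O, M = lines[0].split()
        if tag != "SFAM":
            raise ValueError
        d, O, M = int(d), int(O), int(M)
    except (ValueError, IndexError):
        raise ValueError("malformed bundle: expected header line 'SFAM d O M'") from None
    if len(lines) != 4 + O:
        raise ValueError(f"malformed bundle: expected {4 + O} lines, found {len(lines)}")

    def _vals(line: str, tag: str, n: int) -> np.ndarray:
        parts = line.split()
        if parts[0] != tag or len(parts) != n + 1:
            raise ValueError(f"malformed bundle: bad {tag} line")
        return np.array([float(p) for p in parts[1:]], dtype=np.float32)

    mins = _vals(lines[1], "MIN", d)
    maxs = _vals(lines[2], "MAX", d)
    weights = np.stack([_vals(lines[3 + j], "W", 2 * d) for j in range(O)])
    mapfield = _vals(lines[3 + O], "MAP", O).astype(int)
    if mapfield.min() < 1 or mapfield.max() > M:
        raise ValueError("corrupted bundle: mapfield labels outside 1..M")
    return SFAMModel(
        d=d,
        params=SFAMParams(),
        scaler=FeatureScaler(mins=mins.astype(float), maxs=maxs.astype(float)),
        n_classes=M,
        weights=weights.astype(float),
        mapfield=mapfield,
    )


@dataclass(frozen=True)
class FootprintReport:
    """Bytes needed on-device for each artifact and their total."""

    weights_bytes: int
    mapfield_bytes: int
    scaler_bytes: int

    @property
    def total_bytes(self) -> int:
        return self.weights_bytes + self.mapfield_bytes + self.scaler_bytes


def memory_footprint(
    model: SFAMModel, value_width_bytes: int = 4, label_width_bytes: int = 1
) -> FootprintReport:
    """O*2d values + O labels + 2d scaler extrema at the given widths."""
    O, d = model.mapfield_size, model.d
    return FootprintReport(
        weights_bytes=O * 2 * d * value_width_bytes,
        mapfield_bytes=O * label_width_bytes,
        scaler_bytes=2 * d * value_width_bytes,
    )


def standalone_predict(bundle: ExportBundle, x) -> int:
    """Device-style inference from the bundle alone, in float32 arithmetic.

    Normalize with the bundle's min/max (clipping), complement-code,
    and return the mapfield label of the category maximizing
    T = |I ^ w| / (alpha + |w|) (ties -> lowest index).  Written as
    plain loops over the bundle's float32 values, mirroring the
    firmware routine rather than the training implementation.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.shape != (bundle.d,):
        raise ValueError(f"expected {bundle.d} features, got {x.shape}")
    alpha = np.float32(0.001)
    one = np.float32(1.0)
    a = np.empty(2 * bundle.d, dtype=np.float32)
    for i in range(bundle.d):
        lo, hi = bundle.mins[i], bundle.maxs[i]
        v = np.float32(0.0) if hi <= lo else (x[i] - lo) / (hi - lo)
        v = min(max(v, np.float32(0.0)), one)
        a[i] = v
        a[i + bundle.d] = one - v
    best_T = -np.inf
    best_j = 0
    for j in range(bundle.O):
        overlap = np.float32(0.0)
        norm = np.float32(0.0)
        for k in range(2 * bundle.d):
            w = bundle.weights[j, k]
            overlap += a[k] if a[k] < w else w
            norm += w
        T = overlap / (alpha + norm)
        if T > best_T:
            best_T = T
            best_j = j
    return int(bundle.mapfield[best_j])
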