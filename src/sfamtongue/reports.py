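"""Test-phase evaluation reports.

The deployment-style report lists, per replicate group, the predicted
class of each assay in row order alongside the group's recognition
rate, then the overall rate and the full confusion matrix — the layout
an operator compares against the class coding sheet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import TongueDataset
from .model_selection import confusion_matrix, recognition_rate
from .sfam import SFAMModel

__all__ = ["EvaluationReport", "evaluate_model"]


@dataclass(frozen=True)
class EvaluationReport:
    group_names: tuple[str, ...]
    group_true: tuple[tuple[int, ...], ...]
    group_pred: tuple[tuple[int, ...], ...]
    group_rates: tuple[float, ...]
    overall_rate: float
    confusion: np.ndarray

    def to_text(self) -> str:
        lines = ["Sample\tClass\tRate"]
        for name, pred, rate in zip(self.group_names, self.group_pred, self.group_rates):
            lines.append(f"{name}\t{' '.join(map(str, pred))}\t{rate:.1f}%")
        lines.append(f"Overall\t\t{self.overall_rate:.1f}%")
        lines.append("")
        lines.append("Confusion matrix (rows: true class, columns: predicted)")
        for i, row in enumerate(self.confusion, start=1):
            lines.append(f"{i}\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


def evaluate_model(model: SFAMModel, test: TongueDataset) -> EvaluationReport:
    """Predict every test assay and aggregate per replicate group.

    The overall rate is the micro-average over all samples, i.e.
    :func:`recognition_rate` of the concatenated per-group vectors.
    """
    if test.n_features != model.d:
        raise ValueError(
            f"model expects {model.d} electrodes, test data has {test.n_features}"
        )
    names, trues, preds, rates = [], [], [], []
    for g in test.group_order:
        sub = test.subset_groups([g])
        p = model.predict_batch(sub.X)
        names.append(g)
        trues.append(tuple(int(v) for v in sub.y))
        preds.append(tuple(int(v) for v in p))
        rates.append(recognition_rate(sub.y, p))
    y_true = np.concatenate([np.array(t) for t in trues])
    y_pred = np.concatenate([np.array(p) for p in preds])
    n_classes = max(model.n_classes, int(y_true.max()))
    return EvaluationReport(
        group_names=tuple(names),
        group_true=tuple(trues),
        group_pred=tuple(preds),
        group_rates=tuple(rates),
        overall_rate=recognition_rate(y_true, y_pred),
        confusion=confusion_matrix(y_true, y_pred, n_classes),
    )
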