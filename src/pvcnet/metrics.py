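"""Binary confusion matrix and the derived metric set.

PVC is the positive class.  With TP/FP/TN/FN the usual counts,

    precision = TP/(TP+FP)           recall      = TP/(TP+FN)
    F1        = 2PR/(P+R)            specificity = TN/(TN+FP)
    accuracy  = (TP+TN)/total        balanced accuracy = (recall+specificity)/2

Per-class values are computed with each class in turn as positive; macro
averages are unweighted means over the two classes.  Balanced accuracy is
computed from exact class recalls on the raw counts, never from
pre-rounded table entries.  Zero-denominator metrics are reported as None
with a flag rather than silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .records import BeatLabel

_LABEL_TO_INT = {BeatLabel.NORMAL: 0, BeatLabel.PVC: 1, "NORMAL": 0, "PVC": 1, 0: 0, 1: 1}


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts over {NORMAL, PVC}; PVC is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    def as_table(self) -> np.ndarray:
        """Rows true (N, PVC), columns predicted (N, PVC)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=np.int64)

    @classmethod
    def from_table(cls, table: np.ndarray) -> "ConfusionMatrix":
        t = np.asarray(table, dtype=np.int64)
        return cls(tp=int(t[1, 1]), fp=int(t[0, 1]), tn=int(t[0, 0]), fn=int(t[1, 0]))


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Exact 2x2 counts from paired label sequences."""
    t = [_to_int(v) for v in true_labels]
    p = [_to_int(v) for v in predicted_labels]
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    t = np.asarray(t)
    p = np.asarray(p)
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _to_int(v) -> int:
    try:
        return _LABEL_TO_INT[v]
    except (KeyError, TypeError):
        raise ValueError(f"label {v!r} outside the binary {{NORMAL, PVC}} set") from None


@dataclass
class ClassMetrics:
    precision: float | None
    recall: float | None
    f1: float | None
    specificity: float | None


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    macro_precision: float | None
    macro_recall: float | None
    macro_f1: float | None
    macro_specificity: float | None
    balanced_accuracy: float | None
    undefined: set[str] = field(default_factory=set)

    def summary(self) -> str:
        lines = [
            f"{'class':>8} {'precision':>10} {'recall':>10} {'F1':>10} {'specificity':>12}"
        ]
        for name, m in self.per_class.items():
            lines.append(
                f"{name:>8} {_fmt(m.precision):>10} {_fmt(m.recall):>10} "
                f"{_fmt(m.f1):>10} {_fmt(m.specificity):>12}"
            )
        lines.append(
            f"{'macro':>8} {_fmt(self.macro_precision):>10} {_fmt(self.macro_recall):>10} "
            f"{_fmt(self.macro_f1):>10} {_fmt(self.macro_specificity):>12}"
        )
        lines.append(
            f"accuracy {_fmt(self.accuracy)}   balanced accuracy {_fmt(self.balanced_accuracy)}"
        )
        if self.undefined:
            lines.append(f"undefined (zero denominator): {sorted(self.undefined)}")
        return "\n".join(lines)


def _fmt(v: float | None) -> str:
    return "undef" if v is None else f"{percent(v):.2f}%"


def percent(value: float, decimals: int = 2) -> float:
    """value in [0,1] -> percentage rounded half away from zero."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Full metric set from a confusion matrix (PVC positive)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix: total count is zero")
    undefined: set[str] = set()

    def safe(num: int, den: int, tag: str) -> float | None:
        if den == 0:
            undefined.add(tag)
            return None
        return num / den

    def one_class(tp: int, fp: int, tn: int, fn: int, name: str) -> ClassMetrics:
        prec = safe(tp, tp + fp, f"{name}.precision")
        rec = safe(tp, tp + fn, f"{name}.recall")
        spec = safe(tn, tn + fp, f"{name}.specificity")
        f1 = safe(2 * tp, 2 * tp + fp + fn, f"{name}.f1")
        return ClassMetrics(prec, rec, f1, spec)

    pvc = one_class(cm.tp, cm.fp, cm.tn, cm.fn, "PVC")
    nrm = one_class(cm.tn, cm.fn, cm.tp, cm.fp, "NORMAL")

    def macro(a: float | None, b: float | None) -> float | None:
        return None if a is None or b is None else (a + b) / 2.0

    bal = macro(pvc.recall, pvc.specificity)
    return MetricsReport(
        per_class={"NORMAL": nrm, "PVC": pvc},
        accuracy=(cm.tp + cm.tn) / cm.total,
        macro_precision=macro(nrm.precision, pvc.precision),
        macro_recall=macro(nrm.recall, pvc.recall),
        macro_f1=macro(nrm.f1, pvc.f1),
        macro_specificity=macro(nrm.specificity, pvc.specificity),
        balanced_accuracy=bal,
        undefined=undefined,
    )
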