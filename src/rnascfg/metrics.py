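"""Structure-comparison metrics and dataset-level aggregation.

A base pair is a true positive if present in both predicted and trusted
structures, a false positive if only predicted, a false negative if only
trusted.  Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), F-score =
2TP/(2TP+FN+FP); each is 0 when its denominator is 0.  Dataset metrics are
micro-averaged (counts summed before ratios) by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decode import Prediction, predict_mea
from .grammar import Grammar, ScfgParams
from .parse import sequence_outside_posteriors
from .structure import Structure, StructuredSequence

__all__ = [
    "MetricReport",
    "compare_structures",
    "mountain_distance",
    "aggregate",
    "relative_metrics",
    "gamma_sweep",
    "default_gamma_grid",
    "combined_best",
]


@dataclass(frozen=True)
class MetricReport:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def fscore(self) -> float:
        denom = 2 * self.tp + self.fn + self.fp
        return 2 * self.tp / denom if denom else 0.0

    def __add__(self, other: "MetricReport") -> "MetricReport":
        return MetricReport(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _as_structure(obj) -> Structure:
    if isinstance(obj, Prediction):
        return obj.structure
    if isinstance(obj, Structure):
        return obj
    raise TypeError(f"expected Structure or Prediction, got {type(obj)!r}")


def compare_structures(predicted: Structure, trusted: Structure) -> MetricReport:
    """Base-pair identity comparison of two equal-length structures."""
    if predicted.length != trusted.length:
        raise ValueError(
            f"length mismatch: predicted {predicted.length} vs trusted {trusted.length}"
        )
    tp = len(predicted.pairs & trusted.pairs)
    return MetricReport(
        tp=tp, fp=len(predicted.pairs) - tp, fn=len(trusted.pairs) - tp
    )


def mountain_distance(s1: Structure, s2: Structure) -> float:
    """L1 distance between the two structures' mountain height profiles.

    The mountain height h(i) is the number of pairs (k, l) with k <= i < l.
    """
    if s1.length != s2.length:
        raise ValueError("length mismatch")

    def heights(s: Structure) -> np.ndarray:
        h = np.zeros(s.length + 1)
        for k, l in s.pairs:
            h[k] += 1
            h[l] -= 1
        return np.cumsum(h[:-1])

    return float(np.abs(heights(s1) - heights(s2)).sum())


def aggregate(
    records: Sequence[StructuredSequence],
    predictions: Sequence,
    macro: bool = False,
) -> MetricReport:
    """Dataset-level metrics: counts summed over records (micro-average).

    With ``macro=True`` returns a report whose ratios are the per-record means
    (encoded by rescaling; tp/fp/fn then lose their count interpretation).
    """
    if not predictions:
        raise ValueError("no predictions supplied")
    if len(records) != len(predictions):
        raise ValueError("records and predictions differ in length")
    reports = [
        compare_structures(_as_structure(p), r.structure)
        for r, p in zip(records, predictions)
    ]
    if not macro:
        total = MetricReport(0, 0, 0)
        for rep in reports:
            total = total + rep
        return total
    return _MacroReport(
        tp=0, fp=0, fn=0,
        _sens=float(np.mean([r.sensitivity for r in reports])),
        _ppv=float(np.mean([r.ppv for r in reports])),
        _f=float(np.mean([r.fscore for r in reports])),
    )


@dataclass(frozen=True)
class _MacroReport(MetricReport):
    _sens: float = 0.0
    _ppv: float = 0.0
    _f: float = 0.0

    @property
    def sensitivity(self) -> float:
        return self._sens

    @property
    def ppv(self) -> float:
        return self._ppv

    @property
    def fscore(self) -> float:
        return self._f


def _id_structure_pairs(predictions) -> list[tuple[str, Structure]]:
    out = []
    for item in predictions:
        if isinstance(item, StructuredSequence):
            out.append((item.id, item.structure))
        else:
            rec_id, struct = item
            out.append((rec_id, _as_structure(struct)))
    return out


def relative_metrics(predictions_a, predictions_b) -> tuple[float, float]:
    """Relative sensitivity and PPV of method A with respect to method B.

    Method A's predictions are scored treating method B's predictions as the
    trusted structures (how well A "predicts" B).  Inputs are sequences of
    ``(id, Structure)`` pairs or :class:`StructuredSequence`; ids must match
    pairwise.
    """
    a = _id_structure_pairs(predictions_a)
    b = _id_structure_pairs(predictions_b)
    if len(a) != len(b) or any(ia != ib for (ia, _), (ib, _) in zip(a, b)):
        raise ValueError("prediction id mismatch between methods")
    total = MetricReport(0, 0, 0)
    for (_, sa), (_, sb) in zip(a, b):
        total = total + compare_structures(sa, sb)
    return total.sensitivity, total.ppv


def default_gamma_grid() -> np.ndarray:
    """γ from 0.05 to 5.00 in increments of 0.05 (100 values)."""
    return np.round(np.arange(1, 101) * 0.05, 10)


def gamma_sweep(
    grammar: Grammar,
    params: ScfgParams,
    records: Sequence[StructuredSequence],
    gamma_grid: Sequence[float] | None = None,
) -> list[tuple[float, float, float]]:
    """Sensitivity/PPV trade-off curve over a γ grid (posterior decoding).

    Posteriors are computed once per record and reused across the grid.
    Records outside the grammar's support contribute all-unpaired predictions
    at every γ.
    """
    if gamma_grid is None:
        gamma_grid = default_gamma_grid()
    gamma_grid = [float(g) for g in gamma_grid]
    if any(g <= 0 for g in gamma_grid):
        raise ValueError("gamma grid must be strictly positive")
    posteriors = []
    for rec in records:
        try:
            posteriors.append(sequence_outside_posteriors(grammar, params, rec.sequence))
        except ValueError:
            posteriors.append(None)
    curve = []
    for gamma in gamma_grid:
        preds = []
        for rec, post in zip(records, posteriors):
            if post is None:
                preds.append(Structure(length=len(rec.sequence)))
            else:
                preds.append(
                    predict_mea(grammar, params, rec.sequence, gamma, posterior=post)
                )
        report = aggregate(records, preds)
        curve.append((gamma, report.sensitivity, report.ppv))
    return curve


def combined_best(
    records: Sequence[StructuredSequence],
    prediction_sets: Sequence[Sequence],
) -> MetricReport:
    """Oracle combination: per record, keep the prediction with the best
    F-score across sets (ties broken by first set), then micro-average."""
    if not prediction_sets:
        raise ValueError("no prediction sets supplied")
    for preds in prediction_sets:
        if len(preds) != len(records):
            raise ValueError("every prediction set must cover every record")
    total = MetricReport(0, 0, 0)
    for idx, rec in enumerate(records):
        best = None
        for preds in prediction_sets:
            rep = compare_structures(_as_structure(preds[idx]), rec.structure)
            if best is None or rep.fscore > best.fscore:
                best = rep
        total = total + best
    return total
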