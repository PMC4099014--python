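"""Alignment quality measures: Precision, Recall, F-Measure and Overall.

Counts follow the usual alignment-evaluation convention: ``n1`` output
pairs, ``n2`` of them correct, ``n3`` gold pairs missed.  Precision is
``n2/n1``, Recall ``n2/(n2+n3)``, F-Measure their harmonic mean, and the
Overall measure ``r * (2 - 1/p)`` estimates the post-alignment manual
effort (removing false pairs and adding missed ones); it can be negative
when precision falls below one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .clustering import Alignment

__all__ = [
    "EvaluationReport",
    "evaluate",
    "report_from_counts",
    "training_fraction",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Counts and quality measures of one alignment run.

    Measures are stored as fractions in [0, 1] (Overall may be negative);
    use :meth:`as_percentages` for display.
    """

    n1: int  # output pairs
    n2: int  # correct output pairs
    n3: int  # missed gold pairs
    precision: float
    recall: float
    f_measure: float
    overall: float

    def as_percentages(self) -> dict:
        return {
            "n1": self.n1,
            "n2": self.n2,
            "n3": self.n3,
            "precision_pct": round(100 * self.precision, 2),
            "recall_pct": round(100 * self.recall, 2),
            "f_measure_pct": round(100 * self.f_measure, 2),
            "overall_pct": round(100 * self.overall, 2),
        }


def report_from_counts(n1: int, n2: int, n3: int) -> EvaluationReport:
    """Derive the four quality measures from the raw counts.

    Degenerate cases follow 0-conventions: an empty output or an empty
    gold standard yields 0 for the affected measures rather than an error.
    """
    if n2 > n1:
        raise ValueError(f"n2 ({n2}) cannot exceed n1 ({n1})")
    if min(n1, n2, n3) < 0:
        raise ValueError("counts must be nonnegative")
    p = n2 / n1 if n1 else 0.0
    r = n2 / (n2 + n3) if (n2 + n3) else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    o = r * (2 - 1 / p) if n1 and p > 0 else 0.0
    return EvaluationReport(n1=n1, n2=n2, n3=n3, precision=p, recall=r, f_measure=f, overall=o)


def _as_pair_set(pairs: Iterable[Tuple[str, str]]) -> set:
    # Unordered pair identity: direction of the correspondence is ignored.
    return {frozenset(p) for p in pairs}


def evaluate(predicted: Alignment, gold: Sequence[Tuple[str, str]]) -> EvaluationReport:
    """Score a predicted alignment against expert-declared gold pairs."""
    gold_set = _as_pair_set(gold)
    if len(gold_set) != len(list(gold)):
        raise ValueError("gold standard contains duplicate pairs")
    pred_set = _as_pair_set(predicted.as_tuples())
    n1 = len(pred_set)
    n2 = len(pred_set & gold_set)
    n3 = len(gold_set - pred_set)
    return report_from_counts(n1, n2, n3)


def training_fraction(
    n_training: int, report: EvaluationReport
) -> float:
    """Share of expert-provided training pairs among all truly equivalent
    pairs, as a percentage: ``100 * |T| / (n2 + n3)``."""
    gold_total = report.n2 + report.n3
    if gold_total == 0:
        raise ValueError("gold standard is empty; training fraction undefined")
    return 100.0 * n_training / gold_total
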