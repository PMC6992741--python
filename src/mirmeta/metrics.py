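"""Confusion-matrix algebra and the CHL evaluation panel.

The panel carries the standard binary-classification metrics (Sn, Sp, Acc,
Precision, F1, MCC) plus two derived quantities used throughout this
package: the normalized Matthews coefficient MCC' = (MCC + 1) / 2, which
maps [-1, 1] onto [0, 1], and the CHL index, the harmonic mean of Acc,
MCC' and F1,

    CHL = 3 * Acc * MCC' * F1 / (Acc*MCC' + MCC'*F1 + F1*Acc).

The CHL index resists the accuracy paradox (a degenerate all-negative
classifier scores high Acc on imbalanced data) while weighting positive
calls more heavily than MCC does.

Undefined metrics are carried as ``None`` and rendered as the literal
string ``"null"`` in reports. Precision and F1 are undefined when the
classifier makes no positive call (TP + FP = 0); the CHL index is undefined
whenever F1 is. MCC with a zero denominator is defined as 0, the
convention for degenerate all-positive/all-negative predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, TextIO

__all__ = [
    "ConfusionCounts",
    "MetricPanel",
    "panel_from_counts",
    "chl_index",
    "counts_from_rates",
    "round4",
    "write_metric_report",
]

#: Rendering of an undefined metric in TSV reports.
NULL = "null"


@dataclass(frozen=True)
class ConfusionCounts:
    """The four outcome counts of a binary evaluation."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricPanel:
    """Full evaluation panel; ``None`` marks an undefined metric."""

    sn: Optional[float]
    sp: Optional[float]
    acc: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    mcc: Optional[float]
    mcc_prime: Optional[float]
    chl: Optional[float]

    def as_row(self) -> dict:
        """Panel as a report row, 4-decimal half-up rounding, ``"null"`` for undefined."""
        return {
            name: (NULL if value is None else round4(value))
            for name, value in (
                ("Sn", self.sn),
                ("Sp", self.sp),
                ("Acc", self.acc),
                ("F1", self.f1),
                ("MCC", self.mcc),
                ("MCCprime", self.mcc_prime),
                ("CHL", self.chl),
            )
        }


def round4(x: float) -> float:
    """Round half-up to 4 decimals (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def chl_index(
    acc: float, mcc_prime: float, f1: float
) -> Optional[float]:
    """Harmonic mean of accuracy, normalized MCC and F1 score.

    Returns ``None`` (undefined) when all three pairwise products vanish,
    i.e. when the harmonic mean's denominator is 0.

    Raises
    ------
    ValueError
        If any input lies outside [0, 1].
    """
    for name, v in (("acc", acc), ("mcc_prime", mcc_prime), ("f1", f1)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    denom = acc * mcc_prime + mcc_prime * f1 + f1 * acc
    if denom == 0.0:
        return None
    return 3.0 * acc * mcc_prime * f1 / denom


def panel_from_counts(counts: ConfusionCounts) -> MetricPanel:
    """Evaluate the full metric panel from confusion counts.

    Sn is undefined when no positives were evaluated, Sp when no negatives
    were; precision/F1 are undefined when the classifier made no positive
    call; MCC is 0 when its denominator vanishes; the CHL index is
    undefined whenever F1 (or Acc / MCC', which cannot happen for a
    non-empty evaluation) is undefined.
    """
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    n = counts.total
    if n == 0:
        raise ValueError("empty evaluation: all confusion counts are zero")

    acc = (tp + tn) / n
    sn = tp / (tp + fn) if tp + fn > 0 else None
    sp = tn / (tn + fp) if tn + fp > 0 else None
    precision = tp / (tp + fp) if tp + fp > 0 else None

    if precision is None or sn is None:
        f1: Optional[float] = None
    elif precision + sn == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * sn / (precision + sn)

    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / mcc_den if mcc_den > 0 else 0.0
    mcc_prime = (mcc + 1.0) / 2.0

    chl = chl_index(acc, mcc_prime, f1) if f1 is not None else None
    return MetricPanel(sn, sp, acc, precision, f1, mcc, mcc_prime, chl)


def _nearest_count(rate: float, n: int) -> int:
    """Integer k in [0, n] minimizing |k/n - rate|; ties go to the larger k."""
    lo = math.floor(rate * n)
    hi = min(lo + 1, n)
    lo = max(lo, 0)
    # tie (exact midpoint) resolves to hi because the comparison is strict
    if abs(lo / n - rate) < abs(hi / n - rate):
        return lo
    return hi


def counts_from_rates(sn: float, sp: float, n_pos: int, n_neg: int) -> ConfusionCounts:
    """Invert printed sensitivity/specificity back to integer counts.

    Finds the TP in [0, n_pos] whose rate is nearest ``sn`` (ties resolved
    to the larger TP) and the analogous TN, then fills FN/FP by complement.
    Useful for reconstructing confusion matrices from published tables that
    print only rates.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    tp = _nearest_count(sn, n_pos)
    tn = _nearest_count(sp, n_neg)
    return ConfusionCounts(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)


REPORT_COLUMNS = ("method", "Sn", "Sp", "Acc", "F1", "MCC", "MCCprime", "CHL")


def write_metric_report(
    rows: Iterable[tuple[str, MetricPanel]],
    handle: TextIO,
    header_comment: Optional[str] = None,
) -> None:
    """Write a TSV metric report; undefined cells are emitted as ``null``."""
    if header_comment:
        handle.write(f"# {header_comment}\n")
    handle.write("\t".join(REPORT_COLUMNS) + "\n")
    for method, panel in rows:
        cells = panel.as_row()
        out = [method] + [
            cells[c] if isinstance(cells[c], str) else f"{cells[c]:.4f}"
            for c in REPORT_COLUMNS[1:]
        ]
        handle.write("\t".join(out) + "\n")
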