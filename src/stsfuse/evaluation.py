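"""Overall and per-score-interval Pearson correlation and MSE.

Pairs are assigned to the five unit intervals of their gold score with
half-open bins [0,1), [1,2), [2,3), [3,4) and a closed last bin [4,5], so
every valid score lands in exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "IntervalStats", "interval_report", "pearson"]

INTERVALS = [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0)]


def pearson(pred: Sequence[float], gold: Sequence[float]) -> Optional[float]:
    """Sample Pearson correlation; ``None`` when undefined (constant input)."""
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape:
        raise ValueError("pred and gold must have equal lengths")
    if pred.size < 2:
        return None
    if np.ptp(pred) == 0.0 or np.ptp(gold) == 0.0:
        return None
    return float(stats.pearsonr(pred, gold).statistic)


@dataclass
class IntervalStats:
    """Per-bin evaluation: pair count, Pearson (or None), MSE (or None)."""

    low: float
    high: float
    count: int
    pearson: Optional[float]
    mse: Optional[float]

    @property
    def label(self) -> str:
        return f"[{self.low:g},{self.high:g}]"


@dataclass
class EvalReport:
    """Overall Pearson/MSE plus the five per-interval statistics."""

    overall_pearson: Optional[float]
    overall_mse: float
    intervals: List[IntervalStats]
    n: int

    def to_dict(self) -> Dict:
        return {
            "n": self.n,
            "overall_pearson": self.overall_pearson,
            "overall_mse": self.overall_mse,
            "intervals": [
                {
                    "interval": iv.label,
                    "count": iv.count,
                    "pearson": iv.pearson,
                    "mse": iv.mse,
                }
                for iv in self.intervals
            ],
        }

    def to_text(self) -> str:
        """Aligned plain-text table, one row per interval plus Overall."""

        def fmt(x: Optional[float]) -> str:
            return "   n/a" if x is None else f"{x:6.4f}"

        lines = [f"{'Interval':<10}{'Count':>7}{'Pearson':>10}{'MSE':>10}"]
        for iv in self.intervals:
            lines.append(
                f"{iv.label:<10}{iv.count:>7}{fmt(iv.pearson):>10}{fmt(iv.mse):>10}"
            )
        lines.append(
            f"{'Overall':<10}{self.n:>7}{fmt(self.overall_pearson):>10}"
            f"{fmt(self.overall_mse):>10}"
        )
        return "\n".join(lines)


def interval_index(gold: float) -> int:
    """Bin index of a gold score under the half-open/closed-top convention."""
    if not (0.0 <= gold <= 5.0):
        raise ValueError(f"gold score {gold} outside [0, 5]")
    return min(int(np.floor(gold)), 4)


def interval_report(pred: Sequence[float], gold: Sequence[float]) -> EvalReport:
    """Build the full evaluation report from aligned prediction/gold lists."""
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape:
        raise ValueError("pred and gold must have equal lengths")
    bins = np.asarray([interval_index(g) for g in gold])
    intervals: List[IntervalStats] = []
    for k, (low, high) in enumerate(INTERVALS):
        sel = bins == k
        count = int(sel.sum())
        if count == 0:
            intervals.append(IntervalStats(low, high, 0, None, None))
            continue
        mse = float(np.mean((pred[sel] - gold[sel]) ** 2))
        intervals.append(
            IntervalStats(low, high, count, pearson(pred[sel], gold[sel]), mse)
        )
    overall_mse = float(np.mean((pred - gold) ** 2)) if pred.size else 0.0
    return EvalReport(
        overall_pearson=pearson(pred, gold),
        overall_mse=overall_mse,
        intervals=intervals,
        n=int(pred.size),
    )
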