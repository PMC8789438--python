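"""Detection metrics for imbalanced two-class trial streams.

With roughly five nontarget trials per target trial, accuracy alone is
uninformative (the all-nontarget classifier scores ~0.84), so the F1 score
over the target class is the headline criterion, alongside hit rate
(recall on targets) and false-alarm rate (fraction of nontargets flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .exceptions import DataError


@dataclass(frozen=True)
class DetectionMetrics:
    """Counts plus the derived ratios; ``f1 = 0`` when there are no hits."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def hit_rate(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else 0.0

    @property
    def false_alarm_rate(self) -> float:
        neg = self.fp + self.tn
        return self.fp / neg if neg else 0.0

    @property
    def precision(self) -> float:
        flagged = self.tp + self.fp
        return self.tp / flagged if flagged else 0.0

    @property
    def f1(self) -> float:
        if self.tp == 0:
            return 0.0
        p, r = self.precision, self.hit_rate
        return 2 * p * r / (p + r)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Half-up rounding at report precision."""
        return {
            k: round_half_up(getattr(self, k), ndigits)
            for k in ("accuracy", "hit_rate", "false_alarm_rate", "f1")
        }


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_metrics(pred_labels, true_labels) -> DetectionMetrics:
    """Counts and ratios from binary predicted vs true labels."""
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.size == 0:
        raise DataError("cannot compute metrics on empty input")
    if pred.shape != true.shape:
        raise DataError("prediction/label length mismatch")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise DataError("labels must be binary")
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    return DetectionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_rates(
    hit: float, fa: float, n_target: int, n_nontarget: int
) -> DetectionMetrics:
    """Reconstruct the full metric set from printed hit/false-alarm rates.

    ``TP = round(hit * n_target)``, ``FP = round(fa * n_nontarget)``; used to
    check published result tables for internal consistency under a known
    class composition.
    """
    if not (0 <= hit <= 1 and 0 <= fa <= 1):
        raise DataError("rates must lie in [0, 1]")
    if n_target <= 0 or n_nontarget <= 0:
        raise DataError("class counts must be positive")
    tp = int(round_half_up(hit * n_target, 0))
    fp = int(round_half_up(fa * n_nontarget, 0))
    return DetectionMetrics(tp=tp, fp=fp, tn=n_nontarget - fp, fn=n_target - tp)
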