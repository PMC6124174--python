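"""Diagnostic-accuracy statistics: confusion matrices, ROC curves, Youden cutoffs.

These are the routines both evaluation pipelines share. The ROC construction
follows the finite-data "best pair of sensitivity and specificity" search: the
candidate thresholds are the distinct observed scores plus one sentinel above
the maximum, positivity at a threshold t means score ≥ t, the AUC is the
Mann–Whitney concordance probability with half credit for ties, and the
Youden-optimal cutoff is the threshold maximising J = sensitivity +
specificity − 1, ties broken toward the lowest threshold (favouring
sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .biochem import LabRecord, ca_p_ratio, round_half_away, truncate_decimal

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "RocResult",
    "classify",
    "combined_rule",
    "confusion",
    "metrics",
    "roc",
    "youden_cutoff",
    "auc_ci",
    "bootstrap_auc_ci",
]

_Z975 = 1.959963984540054  # 97.5% normal quantile


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies of a binary classification against ground truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy as percentages.

    Raw (unrounded) values are the primitives; a metric whose denominator is
    zero is ``None`` (explicitly undefined), never 0. Published tables print
    integers under an ambiguous convention, so both half-away rounding and
    truncation are exposed alongside the raw values.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    _FIELDS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")

    def raw(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in self._FIELDS}

    def rounded(self, ndigits: int = 0) -> dict[str, float | None]:
        """Half-away-from-zero rounding at ``ndigits`` decimals."""
        return {
            name: None if value is None else round_half_away(value, ndigits)
            for name, value in self.raw().items()
        }

    def truncated(self, ndigits: int = 0) -> dict[str, float | None]:
        """Truncation toward zero at ``ndigits`` decimals."""
        return {
            name: None if value is None else truncate_decimal(value, ndigits)
            for name, value in self.raw().items()
        }


@dataclass(frozen=True)
class RocResult:
    """ROC sweep over the distinct observed scores.

    ``thresholds`` ascend; ``sensitivity[i]``/``specificity[i]`` are the
    operating characteristics when positivity is score ≥ thresholds[i], so
    sensitivity is non-increasing along the array. The last threshold is a
    sentinel above the maximum score (sensitivity 0, specificity 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    youden_cutoff: float
    n_pos: int
    n_neg: int

    @property
    def youden_j(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity


def classify(score: float, cutoff: float, positive_if: str = "gte") -> bool:
    """Dichotomise a score at a cutoff.

    ``positive_if`` selects the orientation: ``"gte"`` (score ≥ cutoff; the
    convention for ROC-derived ratio cutoffs, so the published cutoff itself
    classifies positive), ``"gt"`` (strictly above an upper reference limit,
    e.g. hypercalcemia at Ca > 2.65 mmol/L), ``"lt"`` (strictly below a lower
    limit, e.g. hypophosphatemia).
    """
    if not score > 0 or not cutoff > 0:
        raise ValueError("score and cutoff must be > 0")
    if positive_if == "gte":
        return score >= cutoff
    if positive_if == "gt":
        return score > cutoff
    if positive_if == "lt":
        return score < cutoff
    raise ValueError(f"unknown positivity convention {positive_if!r}")


def combined_rule(record: LabRecord, ratio_cutoff: float = 2.71, ca_upper: float = 2.65) -> bool:
    """Combined Ca/P-or-calcium decision rule.

    Positive when at least one of the two biochemical parameters is beyond its
    cutoff: Ca/P ≥ ``ratio_cutoff`` or total Ca strictly above ``ca_upper``.
    """
    return classify(ca_p_ratio(record.ca, record.p), ratio_cutoff, "gte") or classify(
        record.ca, ca_upper, "gt"
    )


def _as_truth(labels: Iterable) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, (bool, np.bool_)):
            out.append(bool(lab))
        elif lab == "case":
            out.append(True)
        elif lab == "control":
            out.append(False)
        else:
            raise ValueError(f"unknown truth label {lab!r}; expected case/control or bool")
    return np.asarray(out, dtype=bool)


def confusion(predictions: Sequence[bool], truth: Sequence) -> ConfusionCounts:
    """Tally a prediction vector against case/control ground truth."""
    pred = np.asarray(list(predictions), dtype=bool)
    true = _as_truth(truth)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {true.size} labels")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def _ratio_pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Diagnostic metrics (percent) from confusion counts."""
    return DiagnosticMetrics(
        sensitivity=_ratio_pct(counts.tp, counts.tp + counts.fn),
        specificity=_ratio_pct(counts.tn, counts.tn + counts.fp),
        ppv=_ratio_pct(counts.tp, counts.tp + counts.fp),
        npv=_ratio_pct(counts.tn, counts.tn + counts.fn),
        accuracy=_ratio_pct(counts.tp + counts.tn, counts.total),
    )


def roc(scores: Sequence[float], truth: Sequence) -> RocResult:
    """ROC sweep, AUC with Hanley–McNeil CI, and the Youden-optimal cutoff."""
    s = np.asarray(list(scores), dtype=float)
    t = _as_truth(truth)
    if s.shape != t.shape:
        raise ValueError("scores and labels differ in length")
    pos, neg = s[t], s[~t]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    if np.unique(s).size < 2:
        raise ValueError("need at least two distinct scores")

    uniq = np.unique(s)
    sentinel = uniq[-1] + max(1.0, abs(uniq[-1]))  # strictly above every score
    thresholds = np.append(uniq, sentinel)

    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # positivity: score >= t. tp = #(pos >= t), tn = #(neg < t), as exact ints.
    tp = pos.size - np.searchsorted(pos_sorted, thresholds, side="left")
    tn = np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / pos.size
    spec = tn / neg.size

    # Mann-Whitney concordance AUC with 0.5 credit for ties.
    ranks = sps.rankdata(s)
    auc = (ranks[t].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)

    se, ci = auc_ci(auc, pos.size, neg.size)
    # maximise J = tp/n1 + tn/n0 − 1 in integer arithmetic so exact ties break
    # toward the first (lowest) threshold rather than on float noise
    j_scaled = tp * neg.size + tn * pos.size
    cutoff = float(thresholds[int(np.argmax(j_scaled))])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        auc_se=se,
        auc_ci95=ci,
        youden_cutoff=cutoff,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def youden_cutoff(result: RocResult) -> float:
    """Threshold maximising J = sensitivity + specificity − 1 (lowest wins ties).

    Recovers the integer tally behind each operating point so that exact ties
    are broken deterministically toward the lowest threshold.
    """
    tp = np.rint(result.sensitivity * result.n_pos).astype(int)
    tn = np.rint(result.specificity * result.n_neg).astype(int)
    j_scaled = tp * result.n_neg + tn * result.n_pos
    return float(result.thresholds[int(np.argmax(j_scaled))])


def auc_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, tuple[float, float]]:
    """Hanley–McNeil standard error and normal-approximation 95% CI for an AUC.

    Uses the exponential-distribution approximation Q1 = A/(2−A),
    Q2 = 2A²/(1+A); the CI is clipped to [0, 1]. Degenerate class sizes raise.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes must be non-empty")
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, auc - _Z975 * se)
    hi = min(1.0, auc + _Z975 * se)
    return se, (lo, hi)


def bootstrap_auc_ci(
    scores: Sequence[float],
    truth: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Stratified-bootstrap alternative to the Hanley–McNeil CI (percentile method)."""
    s = np.asarray(list(scores), dtype=float)
    t = _as_truth(truth)
    pos, neg = s[t], s[~t]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two scores per class to bootstrap")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pb = rng.choice(pos, pos.size, replace=True)
        nb = rng.choice(neg, neg.size, replace=True)
        ranks = sps.rankdata(np.concatenate([pb, nb]))
        aucs[b] = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
            pos.size * neg.size
        )
    lo, hi = np.quantile(aucs, [0.025, 0.975])
    return float(aucs.std(ddof=1)), (float(lo), float(hi))
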