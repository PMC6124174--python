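"""Independent brute-force oracles for the ROC machinery.

These deliberately avoid the package's vectorised implementations: the AUC is
an exhaustive pairwise concordance count and the Youden cutoff an exhaustive
sweep over candidate thresholds, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np


def brute_auc(pos, neg) -> float:
    """Mean over all (pos, neg) pairs of 1[pos > neg] + 0.5 * 1[pos == neg]."""
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_youden(scores, truth) -> float:
    """Exhaustive sweep: candidate thresholds are the distinct scores plus a
    sentinel above the maximum; positivity is score >= t; lowest threshold wins
    ties on J = sens + spec - 1, evaluated in exact rational arithmetic."""
    from fractions import Fraction

    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos, neg = scores[truth], scores[~truth]
    candidates = sorted(set(scores)) + [max(scores) + 1.0]
    best_t, best_j = None, Fraction(-2)
    for t in candidates:
        sens = Fraction(int((pos >= t).sum()), len(pos))
        spec = Fraction(int((neg < t).sum()), len(neg))
        j = sens + spec - 1
        if j > best_j:  # strict: keeps the lowest threshold among ties
            best_t, best_j = t, j
    return float(best_t)


def brute_confusion(predictions, truth) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) by explicit enumeration."""
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and not t:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn
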