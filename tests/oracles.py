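"""Independent brute-force oracles for the ranking metrics.

These deliberately avoid the library code paths (and sklearn): AUC is the
literal pairwise win fraction, and sensitivity-at-specificity is an
exhaustive sweep over all thresholds between distinct adjacent scores.
"""

import numpy as np


def brute_force_auc(scores, labels):
    """Pairwise win fraction with ties counted 1/2 — the definition."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_sn_at_sp(scores, labels, target):
    """Best sensitivity over all thresholds achieving specificity >= target."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cuts = np.r_[uniq.min() - 1.0, (uniq[:-1] + uniq[1:]) / 2.0, uniq.max() + 1.0]
    best = 0.0
    for c in cuts:
        pred = scores > c
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        sp = tn / (tn + fp)
        if sp >= target:
            tp = np.sum(pred & (labels == 1))
            fn = np.sum(~pred & (labels == 1))
            best = max(best, tp / (tp + fn))
    return best
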