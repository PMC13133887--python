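"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities with the most literal possible
procedure (nested loops, explicit enumeration) and never share code with
the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_force_box_profile(mask: np.ndarray, box_sizes):
    """Explicit triple-nested-loop box counting.

    Enumerates every grid box at every scale, measures its mass by direct
    summation, and returns per-scale (count, occupied-mass list).
    """
    mask = (np.asarray(mask) > 0).astype(np.int64)
    a, b, c = mask.shape
    out = {}
    for eps in sorted(int(e) for e in box_sizes):
        masses = []
        for i0 in range(0, a, eps):
            for j0 in range(0, b, eps):
                for k0 in range(0, c, eps):
                    m = int(mask[i0:i0 + eps, j0:j0 + eps, k0:k0 + eps].sum())
                    if m > 0:
                        masses.append(m)
        out[eps] = masses
    return out


def slope_loglog(sizes, counts):
    """Two-point-or-more OLS slope of log N on log(1/eps), via polyfit."""
    return float(np.polyfit(-np.log(np.asarray(sizes, float)),
                            np.log(np.asarray(counts, float)), 1)[0])


def mann_whitney_auc(scores, labels):
    """Pairwise concordance AUC with ties counted half, by double loop."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_by_scan(scores, labels):
    """Exhaustive threshold scan maximising sens + spec - 1."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best_t, best_j = None, -np.inf
    for t in sorted(set(scores)):
        sens = np.mean(scores[labels == 1] >= t)
        spec = np.mean(scores[labels == 0] < t)
        j = sens + spec - 1
        if j > best_j:
            best_t, best_j = t, j
    return best_t


def net_benefit_by_counts(probs, labels, pt):
    """Decision-curve net benefit from explicit classification counts."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    n = len(labels)
    tp = fp = 0
    for p, y in zip(probs, labels):
        if p >= pt:
            if y == 1:
                tp += 1
            else:
                fp += 1
    return tp / n - (fp / n) * pt / (1 - pt)
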