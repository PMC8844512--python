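"""Naive direct-count reference implementations, independent of the package.

Written as plain loops over the sequence so that agreement with the
vectorised implementations is a meaningful check, not a tautology.
"""

import math

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_encode(seq, schema):
    """Direct-count 188D encoding following the documented conventions."""
    L = len(seq)
    vals = []
    for aa in AA:
        vals.append(sum(1 for ch in seq if ch == aa) / L)
    for part in schema.partitions:
        groups = [set(res) for _, res in part.groups]
        for g in groups:
            vals.append(sum(1 for ch in seq if ch in g) / L)
        for j, k in [(0, 1), (1, 2), (2, 0)]:
            cnt = 0
            for i in range(L - 1):
                a, b = seq[i], seq[i + 1]
                if (a in groups[j] and b in groups[k]) or (a in groups[k] and b in groups[j]):
                    cnt += 1
            vals.append(cnt / (L - 1))
        for g in groups:
            pos = [i + 1 for i, ch in enumerate(seq) if ch in g]
            n = len(pos)
            if n == 0:
                vals.extend([0.0] * 5)
            else:
                ms = [
                    1,
                    max(1, math.ceil(0.25 * n)),
                    max(1, math.ceil(0.50 * n)),
                    max(1, math.ceil(0.75 * n)),
                    n,
                ]
                vals.extend(pos[m - 1] / L for m in ms)
    return np.array(vals)


def pairwise_auroc(y_true, scores):
    """Brute-force AUROC: average over all positive-negative pairs, ties 1/2."""
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pooled_t_squared(x, y_labels):
    """Squared pooled-variance two-sample t statistic for one feature."""
    x = np.asarray(x, dtype=float)
    a = x[np.asarray(y_labels) == 0]
    b = x[np.asarray(y_labels) == 1]
    n0, n1 = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n0 + n1 - 2)
    t = (b.mean() - a.mean()) / math.sqrt(sp2 * (1 / n0 + 1 / n1))
    return t * t
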