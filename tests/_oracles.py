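"""Independent brute-force oracles used only by the test suite.

Everything here is written from first principles (loops, explicit rank
assignment, closed forms) and deliberately shares no code path with the
package implementation it cross-checks.
"""

import itertools
import math

import numpy as np


def midranks(values):
    """Average ranks (1-based) by explicit tie-group enumeration."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def bf_kruskal_h(groups):
    pooled = [v for g in groups for v in g]
    N = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (sum(r) / len(g) - (N + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (N * (N + 1))
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (N**3 - N)
    return h if denom == 0 else h / denom


def bf_dunn_z(groups):
    """Pairwise Dunn z statistics, independent arithmetic."""
    pooled = [v for g in groups for v in g]
    N = len(pooled)
    ranks = midranks(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        r = ranks[start:start + len(g)]
        mean_ranks.append(sum(r) / len(g))
        sizes.append(len(g))
        start += len(g)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    var = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        out.append(0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se)
    return out


def bf_holm(pvals):
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 0.0
    for rank, idx in enumerate(order):
        candidate = min(1.0, (n - rank) * pvals[idx])
        running = max(running, candidate)
        adj[idx] = running
    return adj


def bf_balanced_accuracy(confusion):
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    vals = []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = sum(cm[c]) - tp
        fp = sum(cm[:, c]) - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            continue
        sens = tp / (tp + fn)
        if tn + fp == 0:
            vals.append(sens)
        else:
            vals.append((sens + tn / (tn + fp)) / 2.0)
    return sum(vals) / len(vals)


def bf_kappa(confusion):
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    po = sum(cm[i, i] for i in range(cm.shape[0])) / n
    pe = sum(sum(cm[i]) * sum(cm[:, i]) for i in range(cm.shape[0])) / n**2
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)
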