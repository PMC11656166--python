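"""Independent brute-force oracles used by the test suite.

Everything here is written from the plain definitions with explicit loops and
no reuse of the package's implementations, so agreement is meaningful.
"""

import itertools

import numpy as np


def upgma_cophenetic(D):
    """O(n^3) UPGMA by direct averaging over original pairwise distances.

    Returns the n x n cophenetic matrix (merge height at which each pair
    first joins) and the sorted list of merge heights.
    """
    D = np.asarray(D, float)
    n = len(D)
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph, sorted(heights)


def _groups(labels):
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]


def calinski_harabasz(X, labels):
    X = np.asarray(X, float)
    groups = _groups(labels)
    k, n = len(groups), len(X)
    overall = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for g in groups:
        c = X[g].mean(axis=0)
        B += len(g) * np.sum((c - overall) ** 2)
        for i in g:
            W += np.sum((X[i] - c) ** 2)
    if W == 0:
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


def davies_bouldin(X, labels):
    X = np.asarray(X, float)
    groups = _groups(labels)
    cents = [X[g].mean(axis=0) for g in groups]
    s = [np.mean([np.linalg.norm(X[i] - cents[gi]) for i in g])
         for gi, g in enumerate(groups)]
    k = len(groups)
    total = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            r = np.inf if d == 0 else (s[i] + s[j]) / d
            worst = max(worst, r)
        total += worst
    return total / k


def dunn(X, labels):
    X = np.asarray(X, float)
    groups = _groups(labels)
    diam = 0.0
    for g in groups:
        for i, j in itertools.combinations(g, 2):
            diam = max(diam, np.linalg.norm(X[i] - X[j]))
    sep = np.inf
    for ga, gb in itertools.combinations(range(len(groups)), 2):
        for i in groups[ga]:
            for j in groups[gb]:
                sep = min(sep, np.linalg.norm(X[i] - X[j]))
    if diam == 0:
        return np.inf if sep > 0 else np.nan
    return sep / diam


def silhouette(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    groups = _groups(labels)
    scores = []
    for i in range(len(X)):
        own = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = np.inf
        for g in groups:
            if labels[g[0]] == labels[i]:
                continue
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in g]))
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


def holm_sidak(pvals):
    """Direct evaluation of the step-down formula."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def pearson_r(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))
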