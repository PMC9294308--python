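"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over explicit pair enumerations,
deliberately sharing no code path with the package: shortest paths by
Floyd-Warshall relaxation, correlations by numpy.corrcoef per pair, and the
criteria by literal transcription of their definitions.
"""

from __future__ import annotations

import math

import numpy as np


def floyd_warshall(n: int, edges: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by triple-loop relaxation."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (a, b), w in zip(edges, weights):
        d[a, b] = min(d[a, b], w)
        d[b, a] = min(d[b, a], w)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _pair_table(dist) -> dict[tuple[int, int], float]:
    return {
        (int(i), int(j)): float(d) for i, j, d in zip(dist.i, dist.j, dist.d)
    }


def bin_of(d: float, width: float) -> int:
    """0-based half-open (lo, hi] bin index."""
    return max(int(math.ceil(d / width)) - 1, 0)


def brute_pair_counts(labels, dist, width, max_dist, valid):
    """Per-bin within/between pair counts by exhaustive enumeration."""
    n_bins = int(math.ceil(max_dist / width))
    n_w = np.zeros(n_bins, dtype=int)
    n_b = np.zeros(n_bins, dtype=int)
    for (i, j), d in _pair_table(dist).items():
        if d > max_dist or not (valid[i] and valid[j]):
            continue
        if labels[i] == 0 or labels[j] == 0:
            continue
        b = bin_of(d, width)
        if labels[i] == labels[j]:
            n_w[b] += 1
        else:
            n_b[b] += 1
    return n_w, n_b


def brute_dcbc(values, labels, dist, width, max_dist, valid):
    """(weighted dcbc, unweighted dcbc) by literal definition."""
    n_bins = int(math.ceil(max_dist / width))
    sums = {("w", b): [] for b in range(n_bins)}
    sums.update({("b", b): [] for b in range(n_bins)})
    for (i, j), d in _pair_table(dist).items():
        if d > max_dist or not (valid[i] and valid[j]):
            continue
        if labels[i] == 0 or labels[j] == 0:
            continue
        kind = "w" if labels[i] == labels[j] else "b"
        sums[(kind, bin_of(d, width))].append(pearson(values[i], values[j]))
    d_i, prec = [], []
    for b in range(n_bins):
        nw, nb = len(sums[("w", b)]), len(sums[("b", b)])
        if nw == 0 or nb == 0:
            continue
        d_i.append(np.mean(sums[("w", b)]) - np.mean(sums[("b", b)]))
        prec.append(nw * nb / (nw + nb))
    w = np.array(prec) / np.sum(prec)
    return float(np.dot(w, d_i)), float(np.mean(d_i))


def brute_acd(values, labels, dist, max_dist, valid):
    within, between = [], []
    for (i, j), d in _pair_table(dist).items():
        if d > max_dist or not (valid[i] and valid[j]):
            continue
        if labels[i] == 0 or labels[j] == 0:
            continue
        r = pearson(values[i], values[j])
        (within if labels[i] == labels[j] else between).append(r)
    return float(np.mean(within) - np.mean(between))


def brute_homogeneity(values, labels, valid):
    parcel_means = []
    for k in sorted(set(labels) - {0}):
        members = [v for v in range(len(labels)) if labels[v] == k and valid[v]]
        if len(members) < 2:
            continue
        rs = [
            pearson(values[a], values[b])
            for ai, a in enumerate(members)
            for b in members[ai + 1:]
        ]
        parcel_means.append(np.mean(rs))
    return float(np.mean(parcel_means))


def brute_silhouette(values, labels, neighbors, valid):
    """Mean Silhouette by literal per-vertex computation."""
    scores = []
    for v in range(len(labels)):
        k = labels[v]
        if k == 0 or not valid[v]:
            continue
        own = [u for u in range(len(labels)) if labels[u] == k and valid[u] and u != v]
        pool = [
            u
            for nb in neighbors.get(k, ())
            for u in range(len(labels))
            if labels[u] == nb and valid[u]
        ]
        if not own or not pool:
            continue
        w = np.mean([1 - pearson(values[v], values[u]) for u in own])
        b = np.mean([1 - pearson(values[v], values[u]) for u in pool])
        denom = max(w, b)
        scores.append(0.0 if denom == 0 else (b - w) / denom)
    return float(np.mean(scores))
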