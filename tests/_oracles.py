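"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: distances come
from a full O(n^2) matrix, cluster expansion is a plain BFS over that
matrix, and the renumbering convention is re-derived from scratch.
"""

from __future__ import annotations

import collections

import numpy as np


def dbscan_bruteforce(coords: np.ndarray, ids, eps: float, min_pts: int) -> np.ndarray:
    """Classical DBSCAN on a dense distance matrix with ascending-id scan order.

    Core point: >= min_pts neighbors within eps, itself included.  Clusters
    are grown one at a time scanning ids in ascending order; border points
    take the cluster that reached them first.  Final labels are renumbered
    0..k-1 by decreasing size, ties by smallest member id; noise is -1.
    """
    ids = [str(i) for i in ids]
    n = len(ids)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    neighbors = [set(np.flatnonzero(dist[i] <= eps).tolist()) for i in range(n)]
    core = [len(neighbors[i]) >= min_pts for i in range(n)]

    labels = [None] * n  # None = unvisited, -1 = noise
    scan = sorted(range(n), key=lambda i: ids[i])
    cluster = 0
    for start in scan:
        if labels[start] is not None or not core[start]:
            continue
        # grow a new cluster from this seed
        labels[start] = cluster
        queue = collections.deque([start])
        while queue:
            p = queue.popleft()
            if not core[p]:
                continue
            for q in sorted(neighbors[p], key=lambda i: ids[i]):
                if labels[q] is None or labels[q] == -1:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1
    labels = np.array([-1 if lab is None else lab for lab in labels], dtype=int)

    # independent renumbering: size desc, ties by lexicographically smallest id
    final = np.full(n, -1, dtype=int)
    keys = []
    for c in sorted(set(labels.tolist()) - {-1}):
        members = np.flatnonzero(labels == c)
        keys.append((-len(members), min(ids[m] for m in members), c))
    for new, (_, _, old) in enumerate(sorted(keys)):
        final[labels == old] = new
    return final


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index from the contingency table, written out longhand."""
    a = np.asarray(a)
    b = np.asarray(b)
    cats_a = {v: i for i, v in enumerate(sorted(set(a.tolist())))}
    cats_b = {v: i for i, v in enumerate(sorted(set(b.tolist())))}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for x, y in zip(a, b):
        table[cats_a[x], cats_b[y]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = sum(comb2(v) for v in table.ravel())
    sum_a = sum(comb2(v) for v in table.sum(axis=1))
    sum_b = sum(comb2(v) for v in table.sum(axis=0))
    total = comb2(len(a))
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def mean_silhouette(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from explicit pairwise distances (no sklearn)."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    uniq = sorted(set(labels.tolist()))
    scores = []
    for i in range(len(coords)):
        own = labels[i]
        same = (labels == own) & (np.arange(len(coords)) != i)
        if not same.any():
            scores.append(0.0)
            continue
        a = dist[i, same].mean()
        b = min(dist[i, labels == other].mean() for other in uniq if other != own)
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))
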