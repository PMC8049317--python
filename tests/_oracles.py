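"""Independent brute-force oracles, coded directly from the definitions.

These deliberately avoid the package's implementation paths (and scipy's
clustering/statistics helpers) so they can serve as independent checks:
ECDF supremum by breakpoint enumeration, a naive agglomerative
single-linkage Mapper, and exhaustive modularity maximisation.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov
# ---------------------------------------------------------------------------

def brute_force_ks_D(x, y) -> float:
    """sup_t |ECDF_x(t) − ECDF_y(t)| by enumerating all breakpoints."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


# ---------------------------------------------------------------------------
# Mapper
# ---------------------------------------------------------------------------

def naive_pairwise_distance(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean distance rescaled by sqrt(p / k), by loops."""
    n, p = values.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = [c for c in range(p) if not mask[i, c] and not mask[j, c]]
            k = len(shared)
            if k == 0:
                raise ValueError(f"samples {i} and {j} share no observed protein")
            s = sum((values[i, c] - values[j, c]) ** 2 for c in shared)
            D[i, j] = (s * p / k) ** 0.5
    return D


def naive_single_linkage_heights(D: np.ndarray):
    """Agglomerative single linkage; returns the sorted merge heights."""
    clusters = [{i} for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = min(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


def naive_cluster_cut(members, D: np.ndarray, clustering_bins: int):
    """Histogram-gap cut of the single-linkage dendrogram, via components.

    Heights are histogrammed into equal-width bins over [0, max height];
    the cut is the lower edge of the first empty bin above the first
    occupied one, and clusters are the connected components of the graph
    with edges of length <= cut.  No such gap (or zero max height) keeps
    one cluster.
    """
    members = list(members)
    k = len(members)
    if k == 0:
        return []
    if k == 1:
        return [frozenset(members)]
    sub = D[np.ix_(members, members)]
    heights = naive_single_linkage_heights(sub)
    top = max(heights)
    cut = None
    if top > 0:
        counts, edges = np.histogram(heights, bins=clustering_bins, range=(0.0, top))
        occ = [b for b in range(clustering_bins) if counts[b] > 0]
        for b in range(occ[0] + 1, clustering_bins):
            if counts[b] == 0:
                cut = edges[b]
                break
    if cut is None:
        return [frozenset(members)]
    # connected components with edges <= cut
    unseen = set(range(k))
    clusters = []
    while unseen:
        start = min(unseen)
        comp = {start}
        frontier = [start]
        unseen.discard(start)
        while frontier:
            a = frontier.pop()
            for b in list(unseen):
                if sub[a, b] <= cut:
                    comp.add(b)
                    unseen.discard(b)
                    frontier.append(b)
        clusters.append(frozenset(members[i] for i in comp))
    return clusters


def naive_mapper(values, mask, lens1, lens2, intervals, overlap, clustering_bins):
    """Brute-force Mapper: nodes as (bin, member frozenset), edge set.

    Lens vectors are provided (the lens functions themselves are checked
    separately); cover intervals follow L = range / (n − (n−1)g) with
    interval i starting at min + i·L·(1−g), half-open except the last.
    """
    D = naive_pairwise_distance(values, mask) if mask.any() else np.array(
        [[sum((a - b) ** 2 for a, b in zip(values[i], values[j])) ** 0.5
          for j in range(len(values))] for i in range(len(values))]
    )

    def axis(vals, n, g):
        lo, hi = float(min(vals)), float(max(vals))
        if hi <= lo:
            return [(lo, lo)]
        if n == 1:
            return [(lo, hi)]
        L = (hi - lo) / (n - (n - 1) * g)
        ivals = [(lo + i * L * (1 - g), lo + i * L * (1 - g) + L) for i in range(n)]
        # by definition the last interval ends at the lens maximum (closed)
        ivals[-1] = (ivals[-1][0], hi)
        return ivals

    ax1 = axis(lens1, intervals[0], overlap)
    ax2 = axis(lens2, intervals[1], overlap)
    nodes = set()
    for i1, (lo1, hi1) in enumerate(ax1):
        for i2, (lo2, hi2) in enumerate(ax2):
            members = []
            for s in range(len(values)):
                v1, v2 = lens1[s], lens2[s]
                ok1 = (v1 >= lo1) and (v1 <= hi1 if i1 == len(ax1) - 1 else v1 < hi1)
                ok2 = (v2 >= lo2) and (v2 <= hi2 if i2 == len(ax2) - 1 else v2 < hi2)
                if ok1 and ok2:
                    members.append(s)
            for cluster in naive_cluster_cut(members, D, clustering_bins):
                nodes.add(((i1, i2), cluster))
    nodes = sorted(nodes, key=lambda t: (t[0], sorted(t[1])))
    edges = set()
    for a, b in itertools.combinations(range(len(nodes)), 2):
        if nodes[a][1] & nodes[b][1]:
            edges.add((a, b))
    return nodes, edges


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def all_partitions(items):
    """Every set partition of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_of(adj: np.ndarray, partition) -> float:
    """Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j), from the definition."""
    k = adj.sum(axis=1)
    two_m = k.sum()
    label = {}
    for c, comm in enumerate(partition):
        for v in comm:
            label[v] = c
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if label[i] == label[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def max_modularity(adj: np.ndarray) -> float:
    """Exhaustive-search maximum modularity over all partitions."""
    n = adj.shape[0]
    return max(modularity_of(adj, p) for p in all_partitions(range(n)))
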