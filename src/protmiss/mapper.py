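"""Two-lens Mapper for comparing data shapes before and after imputation.

Mapper reduces a high-dimensional sample set to a network: each sample is
placed in a 2-D lens space, the lens space is covered by overlapping
rectangular bins, the pre-image of each bin is clustered (single linkage
with a histogram-gap cut), and each cluster becomes a node; nodes sharing
samples are linked.  Enriching nodes with their members' mean missingness
percentage shows how missingness organises the topology, and comparing
the networks built from non-imputed and imputed matrices shows how much
an imputation method distorts the shape of the data.

Defaults follow the reference configuration for plasma SWATH cohorts:
L∞-eccentricity and first-PPCA-component lenses, Euclidean metric, 50%
overlap, 16 × 15 intervals, 10 histogram bins for the cluster cut.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .matrix import ProteinMatrix
from .profile import MissingnessProfile

__all__ = [
    "MapperConfig",
    "MapperNode",
    "MapperGraph",
    "distance_matrix",
    "lens_eccentricity",
    "lens_ppca_first",
    "build_cover",
    "cover_membership",
    "cluster_preimage",
    "build_mapper",
    "enrich_missingness",
    "detect_communities",
    "compare_topologies",
]

log = logging.getLogger("protmiss")

LENSES = ("l_infinity_eccentricity", "l1_eccentricity", "ppca_first_component")
MISSING_POLICIES = ("pairwise_complete_scaled", "complete_only")

#: Largest graph for which community detection enumerates all partitions.
EXACT_COMMUNITY_MAX_NODES = 12


@dataclass
class MapperConfig:
    """Parameters of the Mapper construction."""

    lens1: str = "l_infinity_eccentricity"
    lens2: str = "ppca_first_component"
    intervals: tuple[int, int] = (16, 15)
    overlap: float = 0.5
    clustering_bins: int = 10
    metric: str = "euclidean"
    missing_policy: str = "pairwise_complete_scaled"

    def __post_init__(self) -> None:
        if self.lens1 not in LENSES or self.lens2 not in LENSES:
            raise ValueError(f"lenses must be among {LENSES}")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        if min(self.intervals) < 1:
            raise ValueError("interval counts must be >= 1")
        if self.clustering_bins < 1:
            raise ValueError("clustering_bins must be >= 1")
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")


@dataclass
class MapperNode:
    node_id: int
    members: list[str]
    bin_index: tuple[int, int]


@dataclass
class MapperGraph:
    """Nodes (sample clusters), edges (shared samples), and annotations."""

    nodes: list[MapperNode]
    edges: list[tuple[int, int]]
    sample_ids: list[str]
    node_enrichment: dict[int, float] = field(default_factory=dict)
    communities: dict[int, int] = field(default_factory=dict)
    modularity: float | None = None
    community_method: str | None = None

    # -- views ---------------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.node_id,
                members=",".join(node.members),
                size=len(node.members),
                bin_index=f"{node.bin_index[0]},{node.bin_index[1]}",
            )
            if node.node_id in self.node_enrichment:
                g.nodes[node.node_id]["missingness_pct"] = self.node_enrichment[node.node_id]
            if node.node_id in self.communities:
                g.nodes[node.node_id]["community"] = self.communities[node.node_id]
        g.add_edges_from(self.edges)
        return g

    def summary(self) -> dict:
        g = self.to_networkx()
        return {
            "n_nodes": len(self.nodes),
            "n_edges": len(self.edges),
            "n_connected_components": nx.number_connected_components(g) if len(self.nodes) else 0,
            "modularity": self.modularity,
            "community_method": self.community_method,
        }

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def node_table(self) -> list[dict]:
        return [
            {
                "node_id": n.node_id,
                "bin_index": list(n.bin_index),
                "n_members": len(n.members),
                "members": n.members,
                "missingness_pct": self.node_enrichment.get(n.node_id),
                "community": self.communities.get(n.node_id),
            }
            for n in self.nodes
        ]

    def sample_partition(self) -> dict[str, int]:
        """Assign each covered sample to its largest containing node.

        Ties break toward the smaller node id, so the partition is
        deterministic.
        """
        best: dict[str, tuple[int, int]] = {}
        for node in self.nodes:
            for s in node.members:
                key = (-len(node.members), node.node_id)
                if s not in best or key < best[s]:
                    best[s] = key
        return {s: nid for s, (_, nid) in best.items()}


# ---------------------------------------------------------------------------
# distances and lenses
# ---------------------------------------------------------------------------

def distance_matrix(m: ProteinMatrix, policy: str = "pairwise_complete_scaled") -> np.ndarray:
    """Euclidean sample–sample distances, tolerant of missing values.

    Complete matrices give plain Euclidean distances.  Otherwise
    ``pairwise_complete_scaled`` computes the distance over co-observed
    proteins and rescales by √(p/k), where k is the number of co-observed
    proteins and p the total — an unbiased-in-expectation completion of
    the squared distance.  ``complete_only`` drops incomplete samples
    (reported in the log) and uses plain distances on the rest; distances
    for dropped samples are NaN rows/columns.
    """
    if policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {policy!r}")
    n, p = m.shape
    if n < 2:
        return np.zeros((n, n))
    if not m.mask.any():
        return squareform(pdist(m.values, metric="euclidean"))

    if policy == "complete_only":
        complete = ~m.mask.any(axis=1)
        dropped = [m.sample_ids[i] for i in np.flatnonzero(~complete)]
        if dropped:
            log.info("complete_only distance: dropping %d incomplete sample(s): %s",
                     len(dropped), dropped[:10])
        D = np.full((n, n), np.nan)
        idx = np.flatnonzero(complete)
        if idx.size >= 2:
            D[np.ix_(idx, idx)] = squareform(pdist(m.values[idx], metric="euclidean"))
        elif idx.size == 1:
            D[idx[0], idx[0]] = 0.0
        return D

    W = (~m.mask).astype(float)
    A = np.where(m.mask, 0.0, m.values)
    A2 = A**2
    # squared distance over co-observed coordinates
    S = (A2 * W) @ W.T + W @ (A2 * W).T - 2.0 * A @ A.T
    K = W @ W.T
    if (K[~np.eye(n, dtype=bool)] == 0).any():
        i, j = np.argwhere((K == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"samples {m.sample_ids[i]!r} and {m.sample_ids[j]!r} share no "
            f"observed protein; cannot compute a pairwise-complete distance"
        )
    np.fill_diagonal(K, 1.0)  # diagonal squared distance is 0 regardless
    D = np.sqrt(np.clip(S, 0.0, None) * (p / K))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def lens_eccentricity(D: np.ndarray, p: float = np.inf) -> np.ndarray:
    """Eccentricity lens: per sample, an aggregate of distances to the others.

    ``p=inf`` (default) is the maximum distance; ``p=1`` the mean distance
    to the other samples.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n == 1:
        return np.zeros(1)
    if not np.isfinite(D).all():
        raise ValueError("eccentricity lens needs a finite distance matrix")
    if np.isinf(p):
        return D.max(axis=1)
    if p == 1:
        return D.sum(axis=1) / (n - 1)
    return ((D**p).sum(axis=1) / (n - 1)) ** (1.0 / p)


def lens_ppca_first(m: ProteinMatrix, seed: int | None = None) -> np.ndarray:
    """First probabilistic-PCA component score per sample.

    Missing cells are completed with the rank-1 PPCA imputation first;
    scores are the first principal component of the completed centred
    matrix.  The sign is fixed so the score correlates positively with
    per-sample mean intensity, making runs comparable.
    """
    from .impute import impute_ppca  # local import to avoid a cycle

    if m.n_samples < 2:
        raise ValueError("ppca lens needs at least 2 samples")
    if m.mask.any():
        completed = impute_ppca(m, n_components=1, seed=seed).completed.values
    else:
        completed = m.values
    Xc = completed - completed.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("degenerate (zero-variance) data: ppca lens undefined")
    scores = U[:, 0] * s[0]
    means = completed.mean(axis=1)
    if np.corrcoef(scores, means)[0, 1] < 0:
        scores = -scores
    return scores


def compute_lens(m: ProteinMatrix, name: str, D: np.ndarray, seed: int | None = None) -> np.ndarray:
    if name == "l_infinity_eccentricity":
        return lens_eccentricity(D, p=np.inf)
    if name == "l1_eccentricity":
        return lens_eccentricity(D, p=1)
    if name == "ppca_first_component":
        return lens_ppca_first(m, seed=seed)
    raise ValueError(f"unknown lens {name!r}")


# ---------------------------------------------------------------------------
# cover
# ---------------------------------------------------------------------------

def _axis_intervals(values: np.ndarray, n: int, overlap: float) -> list[tuple[float, float]]:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        log.warning("zero lens range on an axis; using a single interval")
        return [(lo, lo)]
    if n == 1:
        return [(lo, hi)]
    length = (hi - lo) / (n - (n - 1) * overlap)
    step = length * (1 - overlap)
    out = [(lo + i * step, lo + i * step + length) for i in range(n)]
    # the last right edge equals hi mathematically; snap it so rounding
    # can never leave the lens maximum uncovered
    out[-1] = (out[-1][0], max(out[-1][1], hi))
    return out


def build_cover(
    lens1_values: np.ndarray,
    lens2_values: np.ndarray,
    intervals: tuple[int, int],
    overlap: float,
) -> list[tuple[tuple[int, int], tuple[float, float], tuple[float, float]]]:
    """Overlapping 2-D rectangular cover of the lens space.

    Per axis, ``n`` equal-length intervals span [min, max] with fractional
    overlap ``g``: interval length L = range / (n − (n−1)·g) and interval
    ``i`` starts at min + i·L·(1−g).  The 2-D cover is the cross product;
    intervals are half-open on the right except the last, which is closed
    so the maximum is covered.

    Returns a list of ``((i1, i2), (lo1, hi1), (lo2, hi2))`` bins in
    row-major order.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    ax1 = _axis_intervals(np.asarray(lens1_values, float), intervals[0], overlap)
    ax2 = _axis_intervals(np.asarray(lens2_values, float), intervals[1], overlap)
    return [
        ((i1, i2), r1, r2)
        for (i1, r1), (i2, r2) in itertools.product(enumerate(ax1), enumerate(ax2))
    ]


def cover_membership(
    lens1_values: np.ndarray,
    lens2_values: np.ndarray,
    cover,
) -> list[np.ndarray]:
    """Sample indices falling in each bin.

    Intervals are half-open on the right except the last interval of each
    axis, which is closed, so the lens maximum is always covered and every
    finite lens point lies in at least one bin.
    """
    x1 = np.asarray(lens1_values, float)
    x2 = np.asarray(lens2_values, float)
    n1 = max(i1 for (i1, _), _, _ in cover) + 1
    n2 = max(i2 for (_, i2), _, _ in cover) + 1
    members = []
    for (i1, i2), r1, r2 in cover:
        in1 = (x1 >= r1[0]) & ((x1 <= r1[1]) if i1 == n1 - 1 else (x1 < r1[1]))
        in2 = (x2 >= r2[0]) & ((x2 <= r2[1]) if i2 == n2 - 1 else (x2 < r2[1]))
        members.append(np.flatnonzero(in1 & in2))
    return members


# ---------------------------------------------------------------------------
# pre-image clustering
# ---------------------------------------------------------------------------

def cluster_preimage(
    member_idx: np.ndarray, D_sub: np.ndarray, clustering_bins: int
) -> list[list[int]]:
    """Single-linkage clustering of one bin's pre-image with a histogram cut.

    Merge heights of the single-linkage dendrogram are histogrammed into
    ``clustering_bins`` equal-width bins over [0, max height]; the
    dendrogram is cut at the lower edge of the first empty bin that lies
    above the first occupied one (the standard Mapper gap heuristic —
    leading empty bins, below every merge, are not gaps).  With no such
    empty bin everything stays in one cluster.

    Returns clusters as lists of entries of ``member_idx``, each sorted,
    ordered by their smallest member.
    """
    member_idx = np.asarray(member_idx)
    k = member_idx.size
    if k == 0:
        return []
    if k == 1:
        return [[int(member_idx[0])]]
    condensed = squareform(np.asarray(D_sub, dtype=float), checks=False)
    Z = linkage(condensed, method="single")
    heights = Z[:, 2]
    top = float(heights.max())
    if top <= 0:
        labels = np.ones(k, dtype=int)
    else:
        counts, edges = np.histogram(heights, bins=clustering_bins, range=(0.0, top))
        occupied = np.flatnonzero(counts > 0)
        first_occ = occupied[0]
        gaps = np.flatnonzero((counts == 0) & (np.arange(clustering_bins) > first_occ))
        if gaps.size == 0:
            labels = np.ones(k, dtype=int)
        else:
            cut = float(edges[gaps[0]])
            labels = fcluster(Z, t=cut, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for local, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(int(member_idx[local]))
    out = [sorted(c) for c in clusters.values()]
    out.sort(key=lambda c: c[0])
    return out


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_mapper(
    m: ProteinMatrix,
    cfg: MapperConfig | None = None,
    seed: int | None = None,
    D: np.ndarray | None = None,
) -> MapperGraph:
    """Compose distances → lenses → cover → per-bin clustering → graph.

    Deterministic given the inputs and seed: bins are visited in
    row-major order and clusters ordered by smallest member, so node ids
    are stable.  A precomputed distance matrix may be passed to avoid
    recomputation.
    """
    cfg = cfg or MapperConfig()
    if m.n_samples == 1:
        return MapperGraph(
            nodes=[MapperNode(0, [m.sample_ids[0]], (0, 0))],
            edges=[], sample_ids=list(m.sample_ids),
        )
    if D is None:
        D = distance_matrix(m, cfg.missing_policy)
    if cfg.missing_policy == "complete_only" and np.isnan(D).any():
        keep = ~np.isnan(D).all(axis=1)
        m = m.subset_samples(keep)
        D = D[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))]
    l1 = compute_lens(m, cfg.lens1, D, seed=seed)
    l2 = compute_lens(m, cfg.lens2, D, seed=seed)
    cover = build_cover(l1, l2, cfg.intervals, cfg.overlap)
    membership = cover_membership(l1, l2, cover)

    nodes: list[MapperNode] = []
    seen: set[tuple[tuple[int, int], tuple[int, ...]]] = set()
    node_members_idx: list[list[int]] = []
    for ((bin_idx, _, _), members) in zip(cover, membership):
        if members.size == 0:
            continue
        D_sub = D[np.ix_(members, members)]
        for cluster in cluster_preimage(members, D_sub, cfg.clustering_bins):
            key = (bin_idx, tuple(cluster))
            if key in seen:
                continue
            seen.add(key)
            nodes.append(
                MapperNode(
                    node_id=len(nodes),
                    members=[m.sample_ids[i] for i in cluster],
                    bin_index=bin_idx,
                )
            )
            node_members_idx.append(cluster)

    edges: list[tuple[int, int]] = []
    sets = [set(c) for c in node_members_idx]
    for u in range(len(nodes)):
        for v in range(u + 1, len(nodes)):
            if sets[u] & sets[v]:
                edges.append((u, v))

    return MapperGraph(nodes=nodes, edges=edges, sample_ids=list(m.sample_ids))


def enrich_missingness(g: MapperGraph, profile: MissingnessProfile) -> MapperGraph:
    """Annotate each node with its members' mean missing percentage."""
    lookup = dict(zip(profile.sample_ids, profile.per_sample_fraction))
    for node in g.nodes:
        missing = [s for s in node.members if s not in lookup]
        if missing:
            raise KeyError(f"samples without a profile entry: {missing}")
        g.node_enrichment[node.node_id] = float(
            np.mean([lookup[s] for s in node.members]) * 100.0
        )
    return g


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _modularity_matrix(g: nx.Graph) -> tuple[np.ndarray, list]:
    """Pairwise modularity contributions: Q(partition) = Σ_{i,j same comm} B_ij."""
    nodes = list(g.nodes())
    n = len(nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    k = A.sum(axis=1)
    two_m = k.sum()
    B = (A - np.outer(k, k) / two_m) / two_m
    return B, nodes


def _exact_modularity_partition(B: np.ndarray) -> tuple[list[int], float]:
    """Enumerate all set partitions (restricted-growth strings) maximising Q."""
    n = B.shape[0]
    best_q = -np.inf
    best: list[int] = [0] * n
    labels = [0] * n

    def rec(i: int, n_used: int, q: float) -> None:
        nonlocal best_q, best
        if i == n:
            if q > best_q + 1e-15:
                best_q = q
                best = list(labels)
            return
        for c in range(n_used + 1):
            gain = B[i, i] + 2.0 * sum(B[i, j] for j in range(i) if labels[j] == c)
            labels[i] = c
            rec(i + 1, max(n_used, c + 1), q + gain)
        labels[i] = 0

    rec(0, 0, 0.0)
    return best, float(best_q)


def detect_communities(g: MapperGraph) -> MapperGraph:
    """Modularity-maximising node communities.

    Exact search over all partitions for graphs of ≤ 12 nodes; greedy
    agglomerative modularity (CNM) beyond.  An edgeless graph has no
    defined modularity: each node becomes its own community and modularity
    is reported as 0 by convention.  The method used is recorded in the
    graph summary.
    """
    if not g.nodes:
        raise ValueError("cannot detect communities on an empty graph")
    nxg = g.to_networkx()
    if nxg.number_of_edges() == 0:
        g.communities = {n.node_id: i for i, n in enumerate(g.nodes)}
        g.modularity = 0.0
        g.community_method = "edgeless"
        return g
    if len(g.nodes) <= EXACT_COMMUNITY_MAX_NODES:
        B, order = _modularity_matrix(nxg)
        labels, q = _exact_modularity_partition(B)
        g.communities = {nid: lab for nid, lab in zip(order, labels)}
        g.modularity = q
        g.community_method = "exact"
    else:
        comms = nx.algorithms.community.greedy_modularity_communities(nxg)
        g.communities = {nid: i for i, comm in enumerate(comms) for nid in comm}
        g.modularity = float(
            nx.algorithms.community.modularity(nxg, [set(c) for c in comms])
        )
        g.community_method = "greedy"
    return g


# ---------------------------------------------------------------------------
# topology comparison
# ---------------------------------------------------------------------------

def compare_topologies(g_non_imputed: MapperGraph, g_imputed: MapperGraph) -> dict:
    """Summaries of both graphs plus sample-partition agreement (ARI).

    Each sample is assigned to its largest containing node in each graph;
    the two induced partitions are compared with the adjusted Rand index
    over the samples covered by both.
    """
    p1 = g_non_imputed.sample_partition()
    p2 = g_imputed.sample_partition()
    common = sorted(set(p1) & set(p2))
    if not common:
        raise ValueError("the two graphs cover disjoint sample sets")
    a = [p1[s] for s in common]
    b = [p2[s] for s in common]
    ari = float(adjusted_rand_score(a, b))
    return {
        "non_imputed": g_non_imputed.summary(),
        "imputed": g_imputed.summary(),
        "n_common_samples": len(common),
        "adjusted_rand_index": ari,
    }
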