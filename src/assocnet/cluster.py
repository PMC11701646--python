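"""Network clustering and automatic cluster naming.

Two clustering routes over a confidence-weighted network:

* **k-medoids** on a path-distance matrix.  Edge confidences are turned
  into lengths ``-ln(score)`` so that the shortest path between two nodes
  is the *most probable* path (maximum product of edge confidences under
  independence).  Disconnected networks are handled component-by-component:
  the cluster budget ``k`` is spread over components by repeatedly granting
  one extra cluster to the component that is currently "largest" (node
  count divided by clusters granted so far), i.e. the largest components
  are divided first.
* **MCL**, the Markov cluster algorithm: simulate stochastic flow on the
  column-stochastic score matrix by alternating expansion (matrix squaring)
  and inflation (elementwise power + renormalization); flow condenses into
  attractor regions whose connected components are the clusters.  The
  inflation parameter controls granularity (larger → finer clusters).

Clusters are then *named* by overrepresentation analysis: each cluster's
member genes are tested against the network's node set as background, and
the top terms by enrichment signal become the primary/secondary/tertiary
descriptions, preferring Gene Ontology Biological Process annotations.
Clusters with a single gene, or with no significant term, fall back to
canonical gene names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .enrich import EnrichmentOptions, EnrichmentQuery, TermCollection, run_enrichment
from .errors import InvalidInputError, InvalidParameterError
from .network import Edge, Network


@dataclass
class DistanceMatrix:
    """Symmetric path distances over an explicit node ordering.

    ``matrix[i, j]`` is the length of the most probable path between nodes
    ``ids[i]`` and ``ids[j]`` (in -ln(confidence) units); ``inf`` marks
    unreachable pairs.
    """

    ids: list[str]
    matrix: np.ndarray

    def reachable(self) -> np.ndarray:
        return np.isfinite(self.matrix)


@dataclass
class Clustering:
    """Node → cluster assignment with ids contiguous from 1."""

    assignment: dict[str, int]
    algorithm: str
    parameters: dict = field(default_factory=dict)
    converged: bool = True

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(nodes) for cid, nodes in sorted(out.items())}


@dataclass
class ClusterDescription:
    """Up to three names for a gene set, filled primary-first."""

    primary: str
    secondary: str = ""
    tertiary: str = ""
    source_categories: tuple[str, ...] = ()


def _edge_arrays(network: Network) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    ids = sorted(network.nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    us, vs, ws = [], [], []
    for edge in network.edges:
        if not isinstance(edge, Edge):
            raise InvalidInputError("clustering requires a channel-scored (undirected) network")
        if edge.combined <= 0.0:
            raise InvalidInputError(
                f"edge {edge.u}--{edge.v} has score 0; filter such edges first"
            )
        us.append(index[edge.u])
        vs.append(index[edge.v])
        ws.append(edge.combined)
    return ids, np.array(us, dtype=int), np.array(vs, dtype=int), np.array(ws, dtype=float)


def path_distance_matrix(network: Network) -> DistanceMatrix:
    """All-pairs most-probable-path distances (-ln of the max path probability)."""
    ids, us, vs, ws = _edge_arrays(network)
    n = len(ids)
    lengths = -np.log(ws)
    # sparse graph keeps explicit zero-length edges (score exactly 1) by
    # nudging them to a tiny positive length well below any score resolution
    lengths = np.maximum(lengths, 1e-15)
    graph = csr_matrix((lengths, (us, vs)), shape=(n, n))
    dist = shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(ids, dist)


def _components(network: Network) -> tuple[list[str], np.ndarray, int]:
    ids, us, vs, ws = _edge_arrays(network)
    n = len(ids)
    graph = csr_matrix((np.ones_like(ws), (us, vs)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return ids, labels, n_comp


def _allocate_clusters(sizes: list[int], k: int) -> list[int]:
    """Spread k clusters over components, dividing the largest first.

    Each component starts with one cluster; every extra cluster goes to the
    component maximizing size / clusters-granted (ties: lower component
    index).  Requires k >= len(sizes).
    """
    alloc = [1] * len(sizes)
    for _ in range(k - len(sizes)):
        ratios = [s / a for s, a in zip(sizes, alloc)]
        best = max(range(len(sizes)), key=lambda i: (ratios[i], -i))
        alloc[best] += 1
    return [min(a, s) for a, s in zip(alloc, sizes)]


def _kmedoids_single(D: np.ndarray, b: int, rng: np.random.Generator,
                     max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a full distance matrix.

    Initialization: a seeded random first medoid, then deterministic
    farthest-point seeding (ties: lowest index).  Alternates nearest-medoid
    assignment with exact medoid update until stable.
    """
    n = D.shape[0]
    if b >= n:
        return np.arange(n)
    medoids = [int(rng.integers(n))]
    while len(medoids) < b:
        near = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(near)))
    medoids_arr = np.array(sorted(set(medoids)))
    assign = np.argmin(D[:, medoids_arr], axis=1)
    for _ in range(max_iter):
        new_medoids = []
        for c in range(len(medoids_arr)):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                new_medoids.append(int(medoids_arr[c]))
                continue
            sub = D[np.ix_(members, members)]
            new_medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
        new_medoids_arr = np.array(sorted(set(new_medoids)))
        new_assign = np.argmin(D[:, new_medoids_arr], axis=1)
        if new_medoids_arr.shape == medoids_arr.shape and (
            new_medoids_arr == medoids_arr
        ).all():
            break
        medoids_arr, assign = new_medoids_arr, new_assign
    return assign


def _relabel(ids: list[str], raw: dict[str, int]) -> dict[str, int]:
    """Contiguous cluster ids from 1, ordered by size desc then min node id."""
    groups: dict[int, list[str]] = {}
    for nid in ids:
        groups.setdefault(raw[nid], []).append(nid)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    out: dict[str, int] = {}
    for cid, group in enumerate(ordered, start=1):
        for nid in group:
            out[nid] = cid
    return out


def kmedoids_cluster(network: Network, k: int, seed: int = 0) -> Clustering:
    """Component-aware k-medoids clustering into exactly min(k, n) clusters."""
    n = len(network.nodes)
    if k < 1 or k > n:
        raise InvalidParameterError(f"k must be in [1, {n}], got {k}")
    ids, labels, n_comp = _components(network)
    dm = path_distance_matrix(network)
    comp_nodes = [np.flatnonzero(labels == c) for c in range(n_comp)]
    # component order: size descending, ties by smallest member id
    order = sorted(range(n_comp), key=lambda c: (-comp_nodes[c].size, ids[comp_nodes[c][0]]))
    raw: dict[str, int] = {}
    next_cluster = 0
    if k >= n_comp:
        alloc = _allocate_clusters([comp_nodes[c].size for c in order], k)
        rng = np.random.default_rng(seed)
        for c, budget in zip(order, alloc):
            members = comp_nodes[c]
            sub = dm.matrix[np.ix_(members, members)]
            assign = _kmedoids_single(sub, budget, rng)
            for local, node_idx in enumerate(members):
                raw[ids[node_idx]] = next_cluster + int(assign[local])
            next_cluster += int(assign.max()) + 1
    else:
        # fewer clusters than components: k-1 largest components stand alone,
        # the remainder are lumped together
        for rank, c in enumerate(order):
            cid = rank if rank < k - 1 else k - 1
            for node_idx in comp_nodes[c]:
                raw[ids[node_idx]] = cid
    assignment = _relabel(ids, raw)
    return Clustering(assignment, "kmedoids", {"k": k, "seed": seed})


def mcl_cluster(
    network: Network,
    inflation: float = 2.0,
    pruning: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> Clustering:
    """Markov clustering of a confidence-weighted network.

    Self-loops are added with weight equal to the node's maximum incident
    score (1.0 for isolated nodes); the matrix is column-normalized and
    iterated with expansion (squaring) then inflation (elementwise power
    ``inflation``), pruning entries below ``pruning``, until the matrix
    changes by less than ``tol`` or ``max_iter`` is reached (the result is
    then flagged non-converged).  Deterministic for a fixed input.
    """
    if inflation <= 1.0:
        raise InvalidParameterError(f"inflation must be > 1, got {inflation}")
    ids, us, vs, ws = _edge_arrays(network)
    n = len(ids)
    if n == 0:
        return Clustering({}, "mcl", {"inflation": inflation})
    A = np.zeros((n, n))
    A[us, vs] = ws
    A[vs, us] = ws
    loops = A.max(axis=0)
    loops[loops == 0.0] = 1.0
    np.fill_diagonal(A, loops)
    M = A / A.sum(axis=0)
    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        inflated[inflated < pruning] = 0.0
        col = inflated.sum(axis=0)
        col[col == 0.0] = 1.0
        inflated /= col
        if np.abs(inflated - M).max() < tol:
            M = inflated
            converged = True
            break
        M = inflated
    support = csr_matrix((M + M.T) > 1e-12)
    _, labels = connected_components(support, directed=False)
    raw = {nid: int(lab) for nid, lab in zip(ids, labels)}
    assignment = _relabel(ids, raw)
    return Clustering(
        assignment,
        "mcl",
        {"inflation": inflation, "pruning": pruning, "max_iter": max_iter},
        converged=converged,
    )


def name_gene_set(
    genes: Iterable[str],
    collections: TermCollection | Sequence[TermCollection],
    background: Iterable[str],
    alpha: float = 0.05,
    category_priority: Sequence[str] = ("GO Biological Process",),
    names: Mapping[str, str] | None = None,
    options: EnrichmentOptions | None = None,
) -> ClusterDescription:
    """Describe a gene set by its top enriched terms.

    Runs overrepresentation analysis of ``genes`` against ``background``;
    terms with FDR <= alpha are ranked by enrichment signal, with the
    category priority list as a tie layer (earlier categories win ties;
    Gene Ontology Biological Process is preferred by default).  The top
    three distinct descriptions become primary/secondary/tertiary.  Single
    gene sets, or sets without a significant term, are described by their
    canonical gene names instead.
    """
    genes = sorted(set(genes))
    if not genes:
        raise InvalidInputError("cannot name an empty gene set")
    names = names or {}

    def display(g: str) -> str:
        return names.get(g, g)

    if isinstance(collections, TermCollection):
        collection = collections
    else:
        merged = None
        for coll in collections:
            merged = coll if merged is None else merged.merged(coll)
        collection = merged if merged is not None else TermCollection([])

    if len(genes) > 1 and len(collection) > 0:
        opts = options or EnrichmentOptions()
        opts.alpha = alpha
        query = EnrichmentQuery(frozenset(genes), frozenset(background), opts)
        rows = run_enrichment(query, collection)
        prio = {cat: i for i, cat in enumerate(category_priority)}

        def rank_key(row):
            return (
                -row.signal,
                prio.get(row.term.category, len(category_priority)),
                row.fdr,
                row.term.id,
            )

        eligible = sorted(
            (r for r in rows if r.fdr <= alpha and r.observed >= 1 and r.signal > 0),
            key=rank_key,
        )
        picked: list[tuple[str, str]] = []
        for row in eligible:
            if row.term.description not in [d for d, _ in picked]:
                picked.append((row.term.description, row.term.category))
            if len(picked) == 3:
                break
        if picked:
            descs = [d for d, _ in picked] + ["", ""]
            return ClusterDescription(
                primary=descs[0],
                secondary=descs[1],
                tertiary=descs[2],
                source_categories=tuple(c for _, c in picked),
            )
    # fallback: canonical gene names
    if len(genes) == 1:
        return ClusterDescription(primary=display(genes[0]))
    return ClusterDescription(primary=", ".join(display(g) for g in genes))


def name_clusters(
    clustering: Clustering,
    network: Network,
    collections: TermCollection | Sequence[TermCollection],
    alpha: float = 0.05,
    category_priority: Sequence[str] = ("GO Biological Process",),
    options: EnrichmentOptions | None = None,
) -> dict[int, ClusterDescription]:
    """Name every cluster, with the network's node set as the background."""
    missing = set(clustering.assignment) - set(network.nodes)
    if missing:
        raise InvalidInputError(f"clustering references unknown nodes: {sorted(missing)[:3]}")
    background = set(network.nodes)
    names = network.names()
    out: dict[int, ClusterDescription] = {}
    for cid, members in clustering.members().items():
        out[cid] = name_gene_set(
            members, collections, background, alpha, category_priority, names, options
        )
    return out
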