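"""Community detection by fast greedy modularity optimisation.

The detector is the weighted agglomerative greedy (Clauset-Newman-Moore)
scheme: start from singleton communities and repeatedly merge the pair
of communities with the largest modularity gain while any gain is
positive.  It is implemented natively because determinism requires
owning the tie-breaking: candidate merges are kept in a lazy max-heap
keyed by (-dQ, i, j), so equal gains resolve to the smallest community
index pair and repeated runs give byte-identical partitions.

Weighted modularity of a partition:  Q = sum_c (e_c - a_c^2)  where
e_c is the fraction of total edge weight inside community c and a_c the
fraction of total weighted degree incident to c.

An optional Leiden back-end (python-igraph + leidenalg) is available for
comparison runs; it is stochastic and off the default path.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

from .datatypes import PartitionLabels
from .errors import ValidationError
from .graph import TreeGraph


@dataclass
class CommunityAssignment:
    """Result of community detection: membership, modularity, diagnostics."""

    partition: PartitionLabels
    modularity: float
    degenerate: bool = False   # True when the graph had no edge weight
    method: str = "fastgreedy"
    params: dict = field(default_factory=dict)

    @property
    def assignment(self) -> dict[str, int]:
        return self.partition.assignment

    @property
    def n_communities(self) -> int:
        return self.partition.n_groups


def modularity(graph: TreeGraph, partition: PartitionLabels) -> float:
    """Q = sum_c (e_c - a_c^2) with weighted edges."""
    missing = [n for n in graph.nodes if n not in partition.assignment]
    if missing:
        raise ValidationError(f"partition does not cover node(s) {missing[:5]}")
    m = graph.total_weight()
    if m <= 0.0:
        raise ValidationError("total edge weight is zero; modularity undefined")
    comm = partition.assignment
    e: dict[int, float] = {}
    deg: dict[int, float] = {}
    for u, v, w in graph.edges:
        cu, cv = comm[u], comm[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + w
        deg[cu] = deg.get(cu, 0.0) + w
        deg[cv] = deg.get(cv, 0.0) + w
    q = 0.0
    for c in set(comm.values()):
        q += e.get(c, 0.0) / m - (deg.get(c, 0.0) / (2.0 * m)) ** 2
    return q


def detect_communities(
    graph: TreeGraph,
    method: str = "fastgreedy",
    seed: int | None = None,
    resolution: float = 1.0,
) -> CommunityAssignment:
    """Detect communities on a weighted tree graph.

    ``fastgreedy`` (default) is deterministic; ``leiden`` needs the
    optional leidenalg dependency and a seed.
    """
    if len(graph.nodes) < 1:
        raise ValidationError("graph has no nodes")
    if method == "fastgreedy":
        return _fastgreedy(graph)
    if method == "leiden":
        return _leiden(graph, seed=seed, resolution=resolution)
    raise ValidationError(f"unknown community detection method {method!r}")


def _fastgreedy(graph: TreeGraph) -> CommunityAssignment:
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    m = graph.total_weight()
    if m <= 0.0:
        warnings.warn("graph has no edge weight; every node is a singleton "
                      "community and Q is reported as 0", stacklevel=2)
        part = PartitionLabels.from_groups({n: i for i, n in enumerate(nodes)})
        return CommunityAssignment(part, 0.0, degenerate=True,
                                   params=dict(graph.params))

    # inter-community weights as dict-of-dicts; deg = weighted degree sums
    inter: dict[int, dict[int, float]] = {i: {} for i in range(len(nodes))}
    deg = [0.0] * len(nodes)
    for u, v, w in graph.edges:
        iu, iv = index[u], index[v]
        if iu == iv:
            continue
        inter[iu][iv] = inter[iu].get(iv, 0.0) + w
        inter[iv][iu] = inter[iv].get(iu, 0.0) + w
        deg[iu] += w
        deg[iv] += w

    def gain(i: int, j: int) -> float:
        # dQ of merging communities i and j
        return inter[i].get(j, 0.0) / m - deg[i] * deg[j] / (2.0 * m * m)

    alive = set(range(len(nodes)))
    members: dict[int, list[str]] = {i: [n] for i, n in enumerate(nodes)}
    heap: list[tuple[float, int, int]] = []
    for i in alive:
        for j in inter[i]:
            if i < j:
                heapq.heappush(heap, (-gain(i, j), i, j))

    q = modularity(graph, PartitionLabels.from_groups(
        {n: i for i, n in enumerate(nodes)}))
    while heap:
        neg_dq, i, j = heapq.heappop(heap)
        if i not in alive or j not in alive or j not in inter[i]:
            continue
        dq = gain(i, j)
        if abs(-neg_dq - dq) > 1e-15:     # stale entry; re-queue current value
            heapq.heappush(heap, (-dq, i, j))
            continue
        if dq <= 0.0:
            break
        # merge j into i (i < j by heap construction)
        q += dq
        for k, w in inter[j].items():
            if k == i:
                continue
            inter[i][k] = inter[i].get(k, 0.0) + w
            inter[k][i] = inter[k].get(i, 0.0) + w
            del inter[k][j]
            heapq.heappush(heap, (-gain(min(i, k), max(i, k)), min(i, k), max(i, k)))
        inter[i].pop(j, None)
        for k in list(inter[i]):
            inter[k].pop(j, None)
        deg[i] += deg[j]
        members[i].extend(members.pop(j))
        inter.pop(j)
        alive.discard(j)
        for k in inter[i]:
            heapq.heappush(heap, (-gain(min(i, k), max(i, k)), min(i, k), max(i, k)))

    assignment = {n: i for i, mem in members.items() for n in mem}
    part = PartitionLabels.from_groups(assignment)
    return CommunityAssignment(part, modularity(graph, part),
                               params=dict(graph.params))


def _leiden(graph: TreeGraph, seed: int | None, resolution: float
            ) -> CommunityAssignment:
    try:
        import igraph
        import leidenalg
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ValidationError(
            "leiden backend requires the optional 'python-igraph' and "
            "'leidenalg' dependencies"
        ) from exc
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    g = igraph.Graph(
        n=len(nodes),
        edges=[(index[u], index[v]) for u, v, _ in graph.edges],
    )
    weights = [w for _, _, w in graph.edges]
    part = leidenalg.find_partition(
        g,
        leidenalg.CPMVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed if seed is not None else 0,
    )
    assignment = {nodes[i]: part.membership[i] for i in range(len(nodes))}
    labels = PartitionLabels.from_groups(assignment)
    q = modularity(graph, labels) if graph.total_weight() > 0 else 0.0
    return CommunityAssignment(labels, q, method="leiden",
                               params={**graph.params,
                                       "resolution": resolution, "seed": seed})
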