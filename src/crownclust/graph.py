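"""Rank-product graph construction over per-tree feature vectors.

Per feature, pairwise distances (absolute difference for scalars,
cosine distance for vectors) are converted to standard competition
ranks; the edge weight of a tree pair is the product over features of
(1 - rank/maxrank)^alpha.  Ranking makes the fusion invariant to any
strictly increasing transform of a single feature's distances, which is
what lets incommensurable descriptors be combined without scaling.
The beta share of smallest-weight edges is discarded before community
detection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .datatypes import FEATURE_NAMES, VECTOR_FEATURES, FeatureVector
from .errors import ValidationError


@dataclass
class TreeGraph:
    """Weighted undirected graph over trees (no self-loops)."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    params: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(**self.params)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class PairDistanceTable:
    """Per-feature pairwise distances and competition ranks.

    ``pairs`` lists unordered distinct tree pairs (u < v lexicographically);
    ``distances[f]`` and ``ranks[f]`` align with it; ``max_rank[f]`` is the
    largest rank over all pairs for feature f.
    """

    pairs: list[tuple[str, str]]
    distances: dict[str, np.ndarray]
    ranks: dict[str, np.ndarray]
    max_rank: dict[str, int]


def feature_distance(fu, fv, context: str = "") -> float:
    """Distance between one feature of two trees.

    Scalars: absolute difference.  Vectors: cosine distance
    1 - (u . v)/(|u||v|), in [0, 2]; a zero-norm vector is an error.
    """
    u = np.asarray(fu, dtype=float)
    v = np.asarray(fv, dtype=float)
    if u.ndim == 0 and v.ndim == 0:
        return abs(float(u) - float(v))
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError(f"feature shape mismatch {context}: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValidationError(f"zero-norm feature vector {context}".strip())
    return float(1.0 - float(u @ v) / (nu * nv))


def rank_distances(distances: np.ndarray) -> tuple[np.ndarray, int]:
    """Ascending standard competition ranks ('1224'); ties share the
    smallest applicable rank.  Returns (ranks, max_rank)."""
    d = np.asarray(distances, dtype=float)
    if d.size < 1:
        raise ValidationError("need at least one pairwise distance to rank")
    ranks = rankdata(d, method="min").astype(np.int64)
    return ranks, int(ranks.max())


def pair_distance_table(
    features: Mapping[str, FeatureVector],
    feature_subset: Sequence[str] | None = None,
) -> PairDistanceTable:
    """Compute distances and ranks for every feature over all distinct pairs."""
    subset = tuple(feature_subset) if feature_subset else FEATURE_NAMES
    unknown = [f for f in subset if f not in FEATURE_NAMES]
    if unknown:
        raise ValidationError(f"unknown feature(s) {unknown}; valid: {FEATURE_NAMES}")
    if not subset:
        raise ValidationError("feature subset must be non-empty")
    ids = sorted(features)
    if len(ids) < 2:
        raise ValidationError("need at least 2 trees to build a graph")
    pairs = list(itertools.combinations(ids, 2))

    distances: dict[str, np.ndarray] = {}
    ranks: dict[str, np.ndarray] = {}
    max_rank: dict[str, int] = {}
    for name in subset:
        vals = {tid: np.asarray(features[tid].component(name), float) for tid in ids}
        if name in VECTOR_FEATURES:
            mat = np.vstack([vals[tid] for tid in ids])
            norms = np.linalg.norm(mat, axis=1)
            bad = [ids[i] for i in np.nonzero(norms == 0.0)[0]]
            if bad:
                raise ValidationError(
                    f"zero-norm feature {name!r} for tree(s) {bad}"
                )
            sim = (mat @ mat.T) / np.outer(norms, norms)
            iu = np.triu_indices(len(ids), k=1)
            d = 1.0 - sim[iu]
        else:
            vec = np.array([float(vals[tid]) for tid in ids])
            iu = np.triu_indices(len(ids), k=1)
            d = np.abs(vec[iu[0]] - vec[iu[1]])
        distances[name] = d
        ranks[name], max_rank[name] = rank_distances(d)
    return PairDistanceTable(pairs=pairs, distances=distances, ranks=ranks,
                             max_rank=max_rank)


def edge_weights(table: PairDistanceTable, alpha: float = 2.0) -> np.ndarray:
    """w_uv = prod_f (1 - R_f(u,v)/maxR_f)^alpha over the active features.

    With alpha = 0 every weight is exactly 1 (0^0 == 1 for the max-rank
    factor), so only the graph topology carries information.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    w = np.ones(len(table.pairs))
    for name, r in table.ranks.items():
        base = 1.0 - r / table.max_rank[name]
        w *= np.power(base, alpha)
    return w


def prune_edges(
    nodes: Sequence[str],
    weighted_pairs: Sequence[tuple[str, str, float]],
    beta: float,
    params: dict | None = None,
    order_keys: Sequence[float] | None = None,
) -> TreeGraph:
    """Discard the beta share of smallest-weight edges.

    Edges are sorted ascending by (order key, lexicographic pair) and the
    first floor(beta * |E|) removed.  The order key defaults to the edge
    weight; :func:`build_graph` passes the alpha-independent base rank
    product instead, which is order-identical for alpha > 0 and keeps the
    pruning meaningful at alpha = 0 where every weight is exactly 1.
    Zero-key edges sort first, so they count toward the pruned share, and
    any that survive the quota are removed as well (they carry no
    modularity signal).
    """
    if not (0.0 <= beta < 1.0):
        raise ValidationError("beta must lie in [0, 1)")
    if order_keys is None:
        order_keys = [w for _, _, w in weighted_pairs]
    if len(order_keys) != len(weighted_pairs):
        raise ValidationError("order_keys must align with weighted_pairs")
    decorated = sorted(
        zip(order_keys, weighted_pairs),
        key=lambda kv: (kv[0], (kv[1][0], kv[1][1])),
    )
    n_prune = int(math.floor(beta * len(decorated)))
    kept = [e for k, e in decorated[n_prune:] if k > 0.0]
    kept.sort(key=lambda e: (e[0], e[1]))
    return TreeGraph(nodes=sorted(nodes), edges=kept, params=dict(params or {}))


def build_graph(
    features: Mapping[str, FeatureVector],
    alpha: float = 2.0,
    beta: float = 0.1,
    feature_subset: Sequence[str] | None = None,
) -> TreeGraph:
    """Full construction: distances -> ranks -> weights -> beta-pruning."""
    table = pair_distance_table(features, feature_subset)
    w = edge_weights(table, alpha)
    base = edge_weights(table, alpha=1.0)   # alpha-independent pruning order
    weighted = [(u, v, float(wi)) for (u, v), wi in zip(table.pairs, w)]
    params = {
        "alpha": float(alpha),
        "beta": float(beta),
        "feature_subset": tuple(feature_subset) if feature_subset else FEATURE_NAMES,
        "n_candidate_edges": len(weighted),
    }
    return prune_edges(sorted(features), weighted, beta, params,
                       order_keys=base.tolist())
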