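"""Semi-automatic species labelling and outlier scoring.

A detected community is labelled by plurality vote over a small sample
of its trees with known ground truth; the label propagates to the
unsampled members, so only a handful of trees per community need manual
inspection.  Outlier candidates are scored two ways: the ascending rank
of a tree's mean edge weight to all other trees (rank 1 = least similar
to everything else), and the size of the candidate's community after
aggressive edge pruning (an isolated candidate has size 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .community import CommunityAssignment, detect_communities
from .datatypes import FeatureVector
from .errors import ValidationError
from .graph import build_graph, edge_weights, pair_distance_table

#: pruning share that isolates outliers in the community-size check
OUTLIER_BETA = 0.7


@dataclass
class VoteResult:
    """Per-community vote outcome and the propagated per-tree labels."""

    community_species: dict[int, str]
    tallies: dict[int, dict[str, int]]
    n_sampled: dict[int, int]
    predicted: dict[str, str]
    sampled_trees: dict[int, list[str]] = field(default_factory=dict)

    def accuracy(self, truth: Mapping[str, str]) -> float:
        hits = sum(1 for t, p in self.predicted.items() if truth.get(t) == p)
        return hits / len(self.predicted)


@dataclass
class OutlierReport:
    """Mean-weight statistics for every tree in a reference set."""

    mean_weight: dict[str, float]
    rank: dict[str, int]          # ascending competition rank, 1 = smallest


def majority_vote(
    communities: CommunityAssignment,
    labels: Mapping[str, str],
    k_per_community: int,
    seed: int,
) -> VoteResult:
    """Label each community by plurality over k sampled ground-truth trees.

    Sampling is uniform without replacement among the community's
    labelled trees, with one independent child seed per community so
    trials are reproducible.  Vote ties go to the lexicographically
    smallest species.  Sampled trees keep their own ground-truth label.
    """
    if k_per_community < 1:
        raise ValidationError("k_per_community must be >= 1")
    assignment = communities.assignment
    groups: dict[int, list[str]] = {}
    for tid in sorted(assignment):
        groups.setdefault(assignment[tid], []).append(tid)
    unlabelled = [c for c, members in groups.items()
                  if not any(t in labels for t in members)]
    if unlabelled:
        raise ValidationError(
            f"communities with no ground-truth labels: {sorted(unlabelled)}"
        )

    community_species: dict[int, str] = {}
    tallies: dict[int, dict[str, int]] = {}
    n_sampled: dict[int, int] = {}
    sampled_trees: dict[int, list[str]] = {}
    predicted: dict[str, str] = {}
    for comm in sorted(groups):
        labelled = [t for t in groups[comm] if t in labels]
        k = min(k_per_community, len(labelled))
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(comm,))
        )
        chosen = sorted(rng.choice(len(labelled), size=k, replace=False).tolist())
        sample = [labelled[i] for i in chosen]
        tally: dict[str, int] = {}
        for t in sample:
            tally[labels[t]] = tally.get(labels[t], 0) + 1
        # plurality; ties -> lexicographically smallest species
        winner = min(tally, key=lambda sp: (-tally[sp], sp))
        community_species[comm] = winner
        tallies[comm] = tally
        n_sampled[comm] = k
        sampled_trees[comm] = sample
        for t in groups[comm]:
            predicted[t] = labels[t] if t in sample else winner
    return VoteResult(community_species, tallies, n_sampled, predicted,
                      sampled_trees)


def mean_weight_report(
    features: Mapping[str, FeatureVector],
    alpha: float = 2.0,
    feature_subset: Sequence[str] | None = None,
) -> OutlierReport:
    """Mean unpruned edge weight and its ascending rank for every tree.

    Weights come from the complete rank-product weight matrix (no
    beta-pruning), averaged over the N-1 partners of each tree.
    """
    ids = sorted(features)
    if len(ids) < 2:
        raise ValidationError("reference set must contain at least 2 trees")
    table = pair_distance_table(features, feature_subset)
    w = edge_weights(table, alpha)
    incident: dict[str, list[float]] = {tid: [] for tid in ids}
    for (u, v), wi in zip(table.pairs, w):
        incident[u].append(float(wi))
        incident[v].append(float(wi))
    # exact summation so trees with identical features tie exactly
    means = {tid: math.fsum(incident[tid]) / (len(ids) - 1) for tid in ids}
    vals = np.array([means[tid] for tid in ids])
    ranks = rankdata(vals, method="min").astype(int)
    return OutlierReport(mean_weight=means,
                         rank={tid: int(r) for tid, r in zip(ids, ranks)})


def outlier_mean_weight_rank(
    features: Mapping[str, FeatureVector],
    candidate: str,
    alpha: float = 2.0,
    feature_subset: Sequence[str] | None = None,
) -> tuple[float, int]:
    """(mean weight, ascending rank) of one candidate within the set."""
    if candidate not in features:
        raise ValidationError(f"candidate {candidate!r} not in feature set")
    report = mean_weight_report(features, alpha, feature_subset)
    return report.mean_weight[candidate], report.rank[candidate]


def outlier_community_size(
    features: Mapping[str, FeatureVector],
    candidate: str,
    alpha: float = 2.0,
    beta: float = OUTLIER_BETA,
    feature_subset: Sequence[str] | None = None,
) -> int:
    """Size of the candidate's community (excluding itself) at a high
    pruning share; 0 means the candidate is isolated."""
    if candidate not in features:
        raise ValidationError(f"candidate {candidate!r} not in feature set")
    graph = build_graph(features, alpha=alpha, beta=beta,
                        feature_subset=feature_subset)
    result = detect_communities(graph)
    comm = result.assignment[candidate]
    size = sum(1 for c in result.assignment.values() if c == comm)
    return size - 1
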