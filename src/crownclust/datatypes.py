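"""Core domain types.

A *tree* is one delineated LiDAR point cloud (coordinates in metres, z up).
A *dataset* is an ordered collection of trees plus an optional species
label map.  The 23-component shape descriptor of a tree is held in
:class:`FeatureVector`, and hard cluster/community assignments in
:class:`PartitionLabels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import EmptyInputError, ValidationError

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6")
#: which features are vectors (cosine distance) vs scalars (absolute difference)
VECTOR_FEATURES = frozenset({"f1", "f3", "f4", "f5"})
FEATURE_LENGTHS = {"f1": 3, "f2": 1, "f3": 6, "f4": 6, "f5": 6, "f6": 1}


@dataclass(frozen=True)
class TreePointCloud:
    """One delineated tree: an (n, 3) array of xyz points in metres."""

    tree_id: str
    points: np.ndarray
    species: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(
                f"tree {self.tree_id!r}: points must be an (n, 3) array, "
                f"got shape {pts.shape}"
            )
        if pts.shape[0] < 1:
            raise EmptyInputError(f"tree {self.tree_id!r}: point cloud is empty")
        if not np.all(np.isfinite(pts)):
            raise ValidationError(
                f"tree {self.tree_id!r}: non-finite coordinates present"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def translated(self, offset: Sequence[float]) -> "TreePointCloud":
        return TreePointCloud(
            self.tree_id, self.points + np.asarray(offset, float), self.species
        )

    def rotated_z(self, angle: float) -> "TreePointCloud":
        """Rotate about the vertical axis through the cloud's centroid."""
        c = self.points.mean(axis=0)
        ca, sa = np.cos(angle), np.sin(angle)
        rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        return TreePointCloud(
            self.tree_id, (self.points - c) @ rot.T + c, self.species
        )


class Dataset:
    """Ordered collection of trees; iteration order is sorted by tree_id."""

    def __init__(
        self,
        trees: Sequence[TreePointCloud],
        label_map: Mapping[str, str] | None = None,
    ) -> None:
        ids = [t.tree_id for t in trees]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate tree_id(s): {dupes}")
        self._trees = {t.tree_id: t for t in trees}
        self._order = sorted(self._trees)
        self.label_map: dict[str, str] = dict(label_map or {})
        # species carried on the clouds themselves also populate the map
        for t in trees:
            if t.species is not None and t.tree_id not in self.label_map:
                self.label_map[t.tree_id] = t.species

    def __len__(self) -> int:
        return len(self._order)

    def __iter__(self) -> Iterator[TreePointCloud]:
        return (self._trees[i] for i in self._order)

    def __getitem__(self, tree_id: str) -> TreePointCloud:
        return self._trees[tree_id]

    @property
    def tree_ids(self) -> list[str]:
        return list(self._order)

    def labels(self) -> dict[str, str]:
        return dict(self.label_map)


@dataclass(frozen=True)
class FeatureVector:
    """The 23-component descriptor F(t) = {f1(3), f2, f3(6), f4(6), f5(6), f6}.

    f1 — pairwise differences of the principal-axis standard deviations (m);
    f2 — rotational-symmetry Jaccard index in (0, 1];
    f3/f4/f5 — six B-spline coefficients each, compressing the per-slice
    symmetry, point-count and maximum-radius profiles;
    f6 — L1 residual of the f3 profile fit (>= 0).
    """

    f1: np.ndarray
    f2: float
    f3: np.ndarray
    f4: np.ndarray
    f5: np.ndarray
    f6: float

    def __post_init__(self) -> None:
        for name in ("f1", "f3", "f4", "f5"):
            arr = np.asarray(getattr(self, name), dtype=float)
            want = FEATURE_LENGTHS[name]
            if arr.shape != (want,):
                raise ValidationError(
                    f"{name} must have length {want}, got shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        for name in ("f2", "f6"):
            val = float(getattr(self, name))
            if not np.isfinite(val):
                raise ValidationError(f"{name} is non-finite")
            object.__setattr__(self, name, val)
        if not (0.0 < self.f2 <= 1.0):
            raise ValidationError(f"f2 must lie in (0, 1], got {self.f2}")
        if self.f6 < 0.0:
            raise ValidationError(f"f6 must be >= 0, got {self.f6}")

    def component(self, name: str) -> np.ndarray | float:
        return getattr(self, name)

    def as_array(self) -> np.ndarray:
        """All 23 components concatenated in f1..f6 order."""
        return np.concatenate(
            [
                self.f1,
                [self.f2],
                self.f3,
                self.f4,
                self.f5,
                [self.f6],
            ]
        )


@dataclass
class PartitionLabels:
    """Hard assignment of every tree to one group, indices contiguous from 0."""

    assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assignment:
            idx = sorted(set(self.assignment.values()))
            if idx != list(range(len(idx))):
                raise ValidationError(
                    f"group indices must be contiguous from 0, got {idx}"
                )

    @classmethod
    def from_groups(cls, assignment: Mapping[str, int]) -> "PartitionLabels":
        """Build from arbitrary integer labels, compressing to 0..k-1.

        Groups are renumbered by their smallest member tree_id so the result
        is a pure function of the grouping, not of the input label values.
        """
        groups: dict[int, list[str]] = {}
        for tid, g in assignment.items():
            groups.setdefault(int(g), []).append(tid)
        ordered = sorted(groups.values(), key=lambda members: min(members))
        out = {tid: i for i, members in enumerate(ordered) for tid in members}
        return cls(out)

    @classmethod
    def from_labels(cls, labels: Mapping[str, str]) -> "PartitionLabels":
        """Build from categorical labels (e.g. species strings)."""
        cats = sorted(set(labels.values()))
        index = {c: i for i, c in enumerate(cats)}
        return cls({tid: index[lab] for tid, lab in labels.items()})

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def items(self):
        return sorted(self.assignment.items())

    def to_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[t] for t in order], dtype=int)
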