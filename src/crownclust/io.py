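"""Readers and writers for point clouds, labels, features, graphs, partitions.

Formats: XYZ text (whitespace or comma delimited, ``#`` comments), PLY
(ascii and binary little-endian via :mod:`trimesh`; writing is ascii at
full double precision), LAS/LAZ behind an optional ``laspy`` import,
CSV label tables, the feature JSON schema below, TSV edge lists and CSV
partitions.

Feature JSON schema::

    {"<tree_id>": {"f1": [..3], "f2": x, "f3": [..6], "f4": [..6],
                   "f5": [..6], "f6": x, "species": "optional"}, ...}
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np

from .datatypes import (
    FEATURE_LENGTHS,
    FEATURE_NAMES,
    Dataset,
    FeatureVector,
    PartitionLabels,
    TreePointCloud,
)
from .errors import EmptyInputError, ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

POINT_SUFFIXES = {".xyz", ".txt", ".ply", ".las", ".laz"}


def _load_xyz(path: Path) -> np.ndarray:
    rows: list[tuple[float, float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 coordinates, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
    if not rows:
        raise EmptyInputError(f"{path}: no points found")
    return np.asarray(rows, dtype=float)


def _load_ply(path: Path) -> np.ndarray:
    import trimesh

    obj = trimesh.load(str(path), file_type="ply", process=False)
    verts = np.asarray(obj.vertices, dtype=float)
    if verts.size == 0:
        raise EmptyInputError(f"{path}: PLY file contains no vertices")
    return verts


def _load_las(path: Path) -> np.ndarray:
    try:
        import laspy
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ValidationError(
            "LAS/LAZ support requires the optional 'laspy' dependency "
            "(pip install crownclust[las])"
        ) from exc
    las = laspy.read(str(path))
    return np.column_stack([np.asarray(las.x), np.asarray(las.y), np.asarray(las.z)])


_LOADERS = {"xyz": _load_xyz, "ply": _load_ply, "las": _load_las}


def load_tree_pointcloud(
    path: str | Path, format: str | None = None, tree_id: str | None = None
) -> TreePointCloud:
    """Read one tree's point cloud; format inferred from the suffix if omitted."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"txt": "xyz", "laz": "las"}.get(suffix, suffix)
    if format not in _LOADERS:
        raise ValidationError(f"unsupported point-cloud format {format!r}")
    points = _LOADERS[format](path)
    return TreePointCloud(tree_id or path.stem, points)


def save_tree_xyz(tree: TreePointCloud, path: str | Path) -> None:
    np.savetxt(path, tree.points, fmt="%.8f")


def save_tree_ply(tree: TreePointCloud, path: str | Path) -> None:
    """Write an ascii PLY with double-precision vertices (lossless at 1e-6 m)."""
    pts = tree.points
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        for x, y, z in pts:
            fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")


def read_labels_csv(path: str | Path) -> dict[str, str]:
    """Read a ``tree_id,species`` CSV into a label map."""
    labels: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "tree_id" not in reader.fieldnames:
            raise SchemaError(f"{path}: labels CSV must have a 'tree_id,species' header")
        if "species" not in reader.fieldnames:
            raise SchemaError(f"{path}: labels CSV missing 'species' column")
        for row in reader:
            labels[row["tree_id"]] = row["species"]
    return labels


def write_labels_csv(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tree_id", "species"])
        for tid in sorted(labels):
            writer.writerow([tid, labels[tid]])


def load_dataset(
    directory: str | Path, labels: str | Path | None = None
) -> Dataset:
    """Load every point-cloud file in *directory* (one tree per file)."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in POINT_SUFFIXES
    )
    if not files:
        raise EmptyInputError(f"{directory}: no point-cloud files found")
    stems = [p.stem for p in files]
    if len(set(stems)) != len(stems):
        dupes = sorted({s for s in stems if stems.count(s) > 1})
        raise ValidationError(f"{directory}: duplicate tree_id(s) across files: {dupes}")
    trees = [load_tree_pointcloud(p) for p in files]
    label_map: dict[str, str] = {}
    if labels is not None:
        raw = read_labels_csv(labels)
        known = {t.tree_id for t in trees}
        for tid, sp in raw.items():
            if tid not in known:
                logger.warning("label for unknown tree_id %r ignored", tid)
            else:
                label_map[tid] = sp
    return Dataset(trees, label_map)


# ---------------------------------------------------------------------------
# feature JSON


def write_feature_json(
    features: Mapping[str, FeatureVector],
    path: str | Path,
    labels: Mapping[str, str] | None = None,
) -> None:
    out: dict[str, dict] = {}
    for tid in sorted(features):
        fv = features[tid]
        rec: dict = {
            "f1": fv.f1.tolist(),
            "f2": fv.f2,
            "f3": fv.f3.tolist(),
            "f4": fv.f4.tolist(),
            "f5": fv.f5.tolist(),
            "f6": fv.f6,
        }
        if labels and tid in labels:
            rec["species"] = labels[tid]
        out[tid] = rec
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=1)


def read_feature_json(
    path: str | Path, external_schema: bool = False
) -> tuple[dict[str, FeatureVector], dict[str, str]]:
    """Read a feature JSON; returns (features, species label map).

    With ``external_schema=True`` a best-effort importer accepts third-party
    layouts: case-insensitive field names, flat 23-vectors under common keys,
    or per-feature lists, falling back to positional splitting.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: top level must be an object keyed by tree_id")
    features: dict[str, FeatureVector] = {}
    labels: dict[str, str] = {}
    for tid, rec in data.items():
        if external_schema:
            rec = _coerce_external_record(tid, rec)
        if not isinstance(rec, dict):
            raise SchemaError(f"{path}: entry {tid!r} is not an object")
        for name in FEATURE_NAMES:
            if name not in rec:
                raise SchemaError(f"{path}: entry {tid!r} missing field {name!r}")
        try:
            fv = FeatureVector(
                f1=np.asarray(rec["f1"], float),
                f2=float(rec["f2"]),
                f3=np.asarray(rec["f3"], float),
                f4=np.asarray(rec["f4"], float),
                f5=np.asarray(rec["f5"], float),
                f6=float(rec["f6"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: entry {tid!r}: {exc}") from exc
        features[tid] = fv
        if isinstance(rec.get("species"), str):
            labels[tid] = rec["species"]
    return features, labels


def _coerce_external_record(tid: str, rec) -> dict:
    """Map an unknown third-party feature record onto our schema."""
    if isinstance(rec, dict):
        lowered = {str(k).lower(): v for k, v in rec.items()}
        if all(name in lowered for name in FEATURE_NAMES):
            out = {name: lowered[name] for name in FEATURE_NAMES}
            if "species" in lowered:
                out["species"] = lowered["species"]
            return out
        for key in ("features", "feature_vector", "f", "values"):
            if key in lowered:
                rec = lowered[key]
                break
    if isinstance(rec, (list, tuple)) and len(rec) == 23:
        flat = [float(v) for v in rec]
        return {
            "f1": flat[0:3],
            "f2": flat[3],
            "f3": flat[4:10],
            "f4": flat[10:16],
            "f5": flat[16:22],
            "f6": flat[22],
        }
    raise SchemaError(f"cannot interpret external feature record for tree {tid!r}")


# ---------------------------------------------------------------------------
# graph + partition files


def write_edge_tsv(graph, path: str | Path) -> None:
    """Write a TSV edge list with a ``# alpha= beta= features=`` header."""
    p = graph.params
    feats = ",".join(p.get("feature_subset", FEATURE_NAMES))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# alpha={p.get('alpha')} beta={p.get('beta')} features={feats}\n")
        for u, v, w in graph.edges:
            fh.write(f"{u}\t{v}\t{w:.12g}\n")


def read_edge_tsv(path: str | Path):
    """Read a TSV edge list written by :func:`write_edge_tsv`."""
    from .graph import TreeGraph

    params: dict = {}
    edges: list[tuple[str, str, float]] = []
    nodes: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("# ").split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        if k in ("alpha", "beta"):
                            params[k] = float(v)
                        elif k == "features":
                            params["feature_subset"] = tuple(v.split(","))
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'u<TAB>v<TAB>weight'")
            u, v, w = parts[0], parts[1], float(parts[2])
            if not math.isfinite(w):
                raise ValidationError(f"{path}:{lineno}: non-finite weight")
            edges.append((u, v, w))
            nodes.update((u, v))
    return TreeGraph(nodes=sorted(nodes), edges=edges, params=params)


def write_partition_csv(partition: PartitionLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tree_id", "community"])
        for tid, comm in partition.items():
            writer.writerow([tid, comm])


def read_partition_csv(path: str | Path) -> PartitionLabels:
    assignment: dict[str, int] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "tree_id" not in reader.fieldnames:
            raise SchemaError(f"{path}: partition CSV must have 'tree_id,community' header")
        for row in reader:
            assignment[row["tree_id"]] = int(row["community"])
    if not assignment:
        raise EmptyInputError(f"{path}: empty partition")
    return PartitionLabels.from_groups(assignment)
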