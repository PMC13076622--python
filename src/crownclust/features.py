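"""Rotation-invariant 3D shape descriptors for delineated trees.

The descriptor set per tree:

* ``f1`` — PCA anisotropy: pairwise differences of the standard
  deviations of the point coordinates projected onto the three principal
  directions (sorted descending, hence non-negative, and invariant to
  any rigid motion of the cloud).
* ``f2`` — global rotational symmetry: the Jaccard index between the
  binarised voxel grid V and its rotationally symmetrised counterpart S
  (a discretised surface of revolution around the vertical axis through
  the centre of mass).  Because V(b) is contained in S(b), f2 equals
  |V(b)| / |S(b)|.
* ``f3/f4/f5`` — per-slice profiles (slice-wise Jaccard symmetry, S
  point counts per slice, maximum point radius per slice), each
  compressed to six cubic B-spline coefficients fitted by unpenalised
  least squares.
* ``f6`` — the L1 residual of the f3 profile fit.

Grid anchoring: the voxel origin sits at the bounding-box minimum,
snapped so the horizontal centre of mass lies at a voxel centre in x and
y.  This makes the radial symmetrisation condition symmetric and the
axis-only degenerate case exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.interpolate import BSpline

from .datatypes import FeatureVector, TreePointCloud
from .errors import CrownClustError, DegenerateTreeError, EmptyInputError, ValidationError

#: minimum viable tree: at least this many points and 2 occupied z-slices
MIN_POINTS = 10
DEFAULT_DELTA = 0.5
#: voxel sizes exercised in the resolution-robustness protocol
SUPPORTED_DELTAS = (0.125, 0.25, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class VoxelGrid:
    """Integer count grid V over the tree's bounding box."""

    delta: float
    origin: np.ndarray          # (3,) corner of voxel (0, 0, 0)
    dims: tuple[int, int, int]
    counts: np.ndarray          # int array of shape dims
    centre: np.ndarray          # centre of mass of the tree's points

    @property
    def centre_index_xy(self) -> tuple[int, int]:
        """(i, j) of the voxel column whose centre is the centre of mass."""
        i = int(round((self.centre[0] - self.origin[0]) / self.delta - 0.5))
        j = int(round((self.centre[1] - self.origin[1]) / self.delta - 0.5))
        return i, j

    def occupied(self) -> set[tuple[int, int, int]]:
        """Occupied voxels in centre-relative lattice coordinates
        (dx, dy, k): shared between V and S for set operations."""
        ic, jc = self.centre_index_xy
        ii, jj, kk = np.nonzero(self.counts)
        return set(zip((ii - ic).tolist(), (jj - jc).tolist(), kk.tolist()))


@dataclass(frozen=True)
class SymmetricGrid(VoxelGrid):
    """Rotationally symmetrised grid S; shares delta, z-layering and centre
    with its source V but may extend further horizontally."""

    max_radius: float = 0.0


@dataclass(frozen=True)
class SliceProfiles:
    """Per-z-slice profiles (slices where both grids are empty are dropped)."""

    jaccard_per_slice: np.ndarray
    points_per_slice: np.ndarray
    max_radius_per_slice: np.ndarray
    slice_positions: np.ndarray   # normalised slice midpoints in (0, 1)

    def __post_init__(self) -> None:
        n = len(self.jaccard_per_slice)
        if not (len(self.points_per_slice) == len(self.max_radius_per_slice)
                == len(self.slice_positions) == n):
            raise ValidationError("slice profiles must have equal lengths")


def pca_feature(tree: TreePointCloud) -> np.ndarray:
    """f1: differences of principal-axis standard deviations [d1-d2, d1-d3, d2-d3].

    Invariant to rigid rotation/translation; rank-deficient clouds are
    allowed (missing directions contribute zero deviation).
    """
    pts = tree.points
    if pts.shape[0] < 2:
        raise DegenerateTreeError(
            f"tree {tree.tree_id!r}: PCA feature needs >= 2 points"
        )
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    d = np.zeros(3)
    d[: len(sv)] = sv / np.sqrt(pts.shape[0])  # population stds, descending
    return np.array([d[0] - d[1], d[0] - d[2], d[1] - d[2]])


def voxelize(tree: TreePointCloud, delta: float = DEFAULT_DELTA) -> VoxelGrid:
    """Count points into an isotropic voxel grid with half-open bins."""
    if delta <= 0:
        raise ValidationError("voxel size delta must be > 0")
    pts = tree.points
    if not np.all(np.isfinite(pts)):
        raise ValidationError(f"tree {tree.tree_id!r}: non-finite coordinates")
    centre = pts.mean(axis=0)
    mins = pts.min(axis=0)
    maxs = pts.max(axis=0)
    origin = np.empty(3)
    # snap x/y so that the centre of mass sits at a voxel centre
    for a in (0, 1):
        m = int(np.ceil((centre[a] - mins[a]) / delta - 0.5))
        origin[a] = centre[a] - (m + 0.5) * delta
    origin[2] = mins[2]
    dims = tuple(int(np.floor((maxs[a] - origin[a]) / delta)) + 1 for a in range(3))
    idx = np.floor((pts - origin) / delta).astype(int)
    counts = np.zeros(dims, dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return VoxelGrid(delta=delta, origin=origin, dims=dims, counts=counts,
                     centre=centre)


def _layer_index(z: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    return np.floor((z - grid.origin[2]) / grid.delta).astype(int)


def symmetrize(tree: TreePointCloud, grid: VoxelGrid) -> SymmetricGrid:
    """Revolve the cloud around the vertical axis through the centre of mass.

    A point l increments every voxel s of its own z-layer whose centre
    satisfies | |s_xy - c_xy| - |l_xy - c_xy| | < delta.  Points are
    binned to z-layers with the same half-open rule as V, so the
    binarised V is contained in the binarised S by construction.  The
    horizontal extent of S is a square of half-width max_radius +
    2*delta centred on c_xy, on the same voxel lattice as V.
    """
    delta = grid.delta
    c = grid.centre
    pts = tree.points
    radii = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    max_radius = float(radii.max())
    half_width = max_radius + 2.0 * delta
    K = int(np.ceil(half_width / delta))
    side = 2 * K + 1
    nz = grid.dims[2]
    origin = np.array([c[0] - (K + 0.5) * delta, c[1] - (K + 0.5) * delta,
                       grid.origin[2]])

    offs = (np.arange(side) - K) * delta    # voxel-centre offsets from c
    rho = np.hypot(offs[:, None], offs[None, :])   # (side, side) radial dist

    layer = _layer_index(pts[:, 2], grid)
    counts = np.zeros((side, side, nz), dtype=np.int64)
    order = np.argsort(layer, kind="stable")
    layer_sorted = layer[order]
    radii_sorted = radii[order]
    boundaries = np.searchsorted(layer_sorted, np.arange(nz + 1))
    for k in range(nz):
        rs = np.sort(radii_sorted[boundaries[k]:boundaries[k + 1]])
        if rs.size == 0:
            continue
        hi = np.searchsorted(rs, rho + delta, side="left")
        lo = np.searchsorted(rs, rho - delta, side="right")
        counts[:, :, k] = hi - lo
    return SymmetricGrid(delta=delta, origin=origin, dims=(side, side, nz),
                         counts=counts, centre=c, max_radius=max_radius)


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A n B| / |A u B| on index sets; both empty -> 1 (identical)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def symmetry_feature(grid: VoxelGrid, sym: SymmetricGrid) -> float:
    """f2: Jaccard index of the binarised V and S (equals |V(b)|/|S(b)|)."""
    occ_v = grid.occupied()
    if not occ_v:
        raise EmptyInputError("voxel grid V is empty")
    return jaccard(occ_v, sym.occupied())


def slice_profiles(
    tree: TreePointCloud, grid: VoxelGrid, sym: SymmetricGrid
) -> SliceProfiles:
    """Per-slice symmetry / point-count / max-radius profiles.

    Slices where both grids are empty are dropped from all three profiles;
    slice positions are the surviving z-midpoints normalised by the full
    grid height, so gaps keep their physical position.
    """
    delta = grid.delta
    c = grid.centre
    nz = grid.dims[2]
    if sym.dims[2] != nz or abs(sym.origin[2] - grid.origin[2]) > 1e-12:
        raise ValidationError("V and S must share z-layering")
    ic_v, jc_v = grid.centre_index_xy
    K = (sym.dims[0] - 1) // 2

    pts = tree.points
    radii = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    layer = _layer_index(pts[:, 2], grid)

    jac, npts, maxr, pos = [], [], [], []
    for k in range(nz):
        vi, vj = np.nonzero(grid.counts[:, :, k])
        si, sj = np.nonzero(sym.counts[:, :, k])
        if vi.size == 0 and si.size == 0:
            continue
        v_set = set(zip((vi - ic_v).tolist(), (vj - jc_v).tolist()))
        s_set = set(zip((si - K).tolist(), (sj - K).tolist()))
        jac.append(jaccard(v_set, s_set))
        npts.append(float(sym.counts[:, :, k].sum()))
        in_slice = radii[layer == k]
        maxr.append(float(in_slice.max()) if in_slice.size else 0.0)
        pos.append((k + 0.5) / nz)
    if not jac:
        raise EmptyInputError("all z-slices are empty")
    return SliceProfiles(
        jaccard_per_slice=np.array(jac),
        points_per_slice=np.array(npts),
        max_radius_per_slice=np.array(maxr),
        slice_positions=np.array(pos),
    )


def _bspline_design(x: np.ndarray, n_coef: int) -> np.ndarray:
    """Cubic B-spline design matrix, uniform open knots, n_coef basis fns."""
    interior = np.linspace(0.0, 1.0, n_coef - 2)[1:-1]
    knots = np.concatenate([np.zeros(4), interior, np.ones(4)])
    return BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()


def fit_profile_spline(
    profile: np.ndarray,
    n_coef: int = 6,
    positions: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Compress a per-slice profile to cubic B-spline coefficients.

    Abscissae default to slice midpoints (i + 0.5)/m on [0, 1];
    coefficients come from an unpenalised linear least-squares fit and
    the second return value is the L1 residual sum |fit - data|.
    Profiles shorter than ``n_coef`` give the minimum-norm solution.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 1:
        raise ValidationError("profile must be a non-empty 1-D array")
    if positions is None:
        positions = (np.arange(y.size) + 0.5) / y.size
    x = np.asarray(positions, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValidationError("slice positions must lie in [0, 1]")
    design = _bspline_design(x, n_coef)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residual_l1 = float(np.abs(design @ coef - y).sum())
    return coef, residual_l1


def extract_features(
    tree: TreePointCloud,
    delta: float = DEFAULT_DELTA,
    n_coef: int = 6,
) -> FeatureVector:
    """Assemble the full 23-component descriptor for one tree."""
    if tree.n_points < MIN_POINTS:
        raise DegenerateTreeError(
            f"tree {tree.tree_id!r}: needs >= {MIN_POINTS} points, "
            f"has {tree.n_points}"
        )
    try:
        f1 = pca_feature(tree)
        grid = voxelize(tree, delta)
        occupied_layers = int(np.count_nonzero(grid.counts.sum(axis=(0, 1))))
        if occupied_layers < 2:
            raise DegenerateTreeError(
                f"tree {tree.tree_id!r}: needs >= 2 occupied z-slices at "
                f"delta={delta}, has {occupied_layers}"
            )
        sym = symmetrize(tree, grid)
        f2 = symmetry_feature(grid, sym)
        prof = slice_profiles(tree, grid, sym)
        f3, res3 = fit_profile_spline(prof.jaccard_per_slice, n_coef,
                                      prof.slice_positions)
        f4, _ = fit_profile_spline(prof.points_per_slice, n_coef,
                                   prof.slice_positions)
        f5, _ = fit_profile_spline(prof.max_radius_per_slice, n_coef,
                                   prof.slice_positions)
    except CrownClustError:
        raise
    except Exception as exc:  # pragma: no cover - defensive context wrapper
        raise CrownClustError(f"feature extraction failed for tree "
                              f"{tree.tree_id!r}: {exc}") from exc
    return FeatureVector(f1=f1, f2=f2, f3=f3, f4=f4, f5=f5, f6=res3)


def extract_all(
    dataset, delta: float = DEFAULT_DELTA, n_coef: int = 6
) -> dict[str, FeatureVector]:
    """Extract features for every tree in a dataset (sorted tree_id order)."""
    return {t.tree_id: extract_features(t, delta, n_coef) for t in dataset}
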