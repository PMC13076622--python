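"""Synthetic tree-crown point clouds with species-level structure.

Each species is a crown radius-vs-height profile: six control radii,
piecewise-linearly interpolated over normalised crown height, revolved
around the vertical axis.  A tree is a volumetric uniform fill of that
solid of revolution (optionally azimuthally modulated for crown
asymmetry) plus a vertical trunk segment, with additive Gaussian jitter.
Interior filling matters: terrestrial LiDAR returns occur throughout
crowns, and the voxel-count features need interior mass.

Two named profile packs ship with the package: ``default10`` (ten
clearly separated species, ten trees each in the standard protocol) and
``hard7`` (seven overlapping species with imbalanced counts
164/183/22/39/158/25/100, the merging regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datatypes import Dataset, TreePointCloud
from .errors import EmptyInputError, ValidationError

#: linear density of the trunk segment (points per metre of trunk)
TRUNK_POINTS_PER_M = 20.0

#: normalised crown heights of the six control radii
_CONTROL_U = np.linspace(0.0, 1.0, 6)


@dataclass(frozen=True)
class SpeciesProfile:
    """Parametric description of one species' crown shape.

    radius_profile: six control radii (m) at normalised crown heights
    0, 0.2, ..., 1 (bottom of crown to tip); height_range: (min, max)
    total tree height (m); trunk_fraction: share of height below the
    crown; density: crown points per m^3; asymmetry: amplitude of the
    azimuthal radius modulation r * (1 + a*cos(az - phi0)); noise_sd:
    Gaussian jitter (m).
    """

    species_id: str
    radius_profile: tuple[float, ...]
    height_range: tuple[float, float]
    trunk_fraction: float = 0.2
    density: float = 50.0
    asymmetry: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if len(self.radius_profile) != 6:
            raise ValidationError("radius_profile must have 6 control radii")
        if any(r < 0 for r in self.radius_profile):
            raise ValidationError("radii must be >= 0")
        lo, hi = self.height_range
        if not (0 < lo <= hi):
            raise ValidationError("height_range must satisfy 0 < min <= max")
        if self.density <= 0:
            raise ValidationError("density must be > 0")
        if not (0 <= self.trunk_fraction < 1):
            raise ValidationError("trunk_fraction must lie in [0, 1)")
        if self.asymmetry < 0:
            raise ValidationError("asymmetry must be >= 0")

    def radius_at(self, u: np.ndarray | float, scale: float = 1.0) -> np.ndarray:
        """Crown radius at normalised crown height u in [0, 1]."""
        return scale * np.interp(u, _CONTROL_U, self.radius_profile)

    def crown_volume(self, height: float) -> float:
        """Analytic volume of the (asymmetry-modulated) solid of revolution.

        The azimuthal average of (r(1 + a cos))^2 is r^2 (1 + a^2/2), so
        V = (1 + a^2/2) * pi * crown_h * integral of r(u)^2 du, with the
        integral exact for the piecewise-linear profile.
        """
        scale = height / ((self.height_range[0] + self.height_range[1]) / 2.0)
        crown_h = height * (1.0 - self.trunk_fraction)
        r = np.asarray(self.radius_profile, float) * scale
        seg = np.diff(_CONTROL_U)
        integral = float(np.sum(seg * (r[:-1] ** 2 + r[:-1] * r[1:] + r[1:] ** 2) / 3.0))
        return (1.0 + self.asymmetry**2 / 2.0) * math.pi * crown_h * integral


def sample_tree(
    profile: SpeciesProfile,
    seed: int,
    tree_id: str | None = None,
    height: float | None = None,
) -> TreePointCloud:
    """Draw one tree from a species profile; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    lo, hi = profile.height_range
    if height is None:
        height = float(rng.uniform(lo, hi))
    scale = height / ((lo + hi) / 2.0)
    trunk_h = height * profile.trunk_fraction
    crown_h = height - trunk_h
    phi0 = float(rng.uniform(0.0, 2.0 * math.pi))

    r_max = scale * max(profile.radius_profile) * (1.0 + profile.asymmetry)
    parts: list[np.ndarray] = []

    if r_max > 0.0:
        n_crown = int(rng.poisson(profile.density * profile.crown_volume(height)))
        parts.append(
            _fill_crown(rng, profile, n_crown, scale, trunk_h, crown_h, phi0, r_max)
        )
    n_trunk = int(rng.poisson(TRUNK_POINTS_PER_M * trunk_h))
    if n_trunk > 0:
        tz = rng.uniform(0.0, trunk_h, n_trunk)
        parts.append(np.column_stack([np.zeros(n_trunk), np.zeros(n_trunk), tz]))

    if not parts or sum(len(p) for p in parts) == 0:
        raise EmptyInputError(
            f"species {profile.species_id!r}: density too low, zero points drawn"
        )
    pts = np.vstack([p for p in parts if len(p)])
    if profile.noise_sd > 0.0:
        pts = pts + rng.normal(0.0, profile.noise_sd, pts.shape)
    return TreePointCloud(
        tree_id or f"{profile.species_id}_seed{seed}", pts, species=profile.species_id
    )


def _fill_crown(rng, profile, n_crown, scale, trunk_h, crown_h, phi0, r_max):
    """Uniform volumetric fill by rejection from the bounding cylinder."""
    out = []
    remaining = n_crown
    while remaining > 0:
        batch = max(256, int(remaining * 2.5))
        u = rng.uniform(0.0, 1.0, batch)          # normalised crown height
        az = rng.uniform(0.0, 2.0 * math.pi, batch)
        radial = profile.radius_at(u, scale) * (
            1.0 + profile.asymmetry * np.cos(az - phi0)
        )
        # accept (u, az) with probability prop. to the local cross-section
        keep = rng.uniform(0.0, 1.0, batch) * r_max**2 < radial**2
        u, az, radial = u[keep], az[keep], radial[keep]
        if len(u) > remaining:
            u, az, radial = u[:remaining], az[:remaining], radial[:remaining]
        rad = radial * np.sqrt(rng.uniform(0.0, 1.0, len(u)))
        out.append(
            np.column_stack(
                [rad * np.cos(az), rad * np.sin(az), trunk_h + u * crown_h]
            )
        )
        remaining -= len(u)
    return np.vstack(out) if out else np.empty((0, 3))


def _child_seed(master_seed: int, counter: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def decimate_tree(tree: TreePointCloud, fraction: float, seed: int) -> TreePointCloud:
    """Uniform random subsample keeping floor(fraction * n) points."""
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("decimate fraction must lie in (0, 1]")
    if fraction == 1.0:
        return tree
    n_keep = max(1, int(math.floor(fraction * tree.n_points)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(tree.n_points, size=n_keep, replace=False))
    return TreePointCloud(tree.tree_id, tree.points[idx], tree.species)


def generate_dataset(
    profiles: Sequence[SpeciesProfile],
    n_per_species: int | Sequence[int],
    seed: int,
    rotate: bool = False,
    decimate: float = 1.0,
) -> Dataset:
    """Generate a labelled forest: ``n_per_species`` trees per profile.

    A single master seed drives per-tree child seeds via a counter, so any
    tree is reproducible independently of the others.  ``rotate`` applies a
    uniform random rotation in [0, 2pi) about each tree's vertical axis;
    ``decimate`` subsamples each cloud to the stated fraction.
    """
    if len(profiles) < 1:
        raise ValidationError("at least one species profile is required")
    if isinstance(n_per_species, int):
        counts = [n_per_species] * len(profiles)
    else:
        counts = list(n_per_species)
        if len(counts) != len(profiles):
            raise ValidationError("n_per_species sequence must match profiles")
    if any(c < 1 for c in counts):
        raise ValidationError("n_per_species must be >= 1")

    trees: list[TreePointCloud] = []
    counter = 0
    for profile, count in zip(profiles, counts):
        for j in range(count):
            tid = f"{profile.species_id}_{j:03d}"
            tree = sample_tree(profile, _child_seed(seed, counter), tree_id=tid)
            aux = np.random.default_rng(_child_seed(seed, counter) + 1)
            if rotate:
                tree = tree.rotated_z(float(aux.uniform(0.0, 2.0 * math.pi)))
            if decimate < 1.0:
                tree = decimate_tree(tree, decimate, _child_seed(seed, counter) + 2)
            trees.append(tree)
            counter += 1
    return Dataset(trees)


# ---------------------------------------------------------------------------
# profile packs


def _with_density(target_points: float, **kwargs) -> SpeciesProfile:
    """Build a profile whose density yields ~target_points crown points
    for a tree at the mean of its height range."""
    probe = SpeciesProfile(density=1.0, **kwargs)
    mean_h = sum(probe.height_range) / 2.0
    vol = probe.crown_volume(mean_h)
    if vol <= 0:
        raise ValidationError(f"{probe.species_id}: zero crown volume")
    return SpeciesProfile(density=round(target_points / vol, 3), **kwargs)


def _default10() -> list[SpeciesProfile]:
    target = 5000.0
    spec = [
        ("conifer_cone", (2.8, 2.4, 1.9, 1.3, 0.7, 0.05), (18, 22), 0.15, 0.0),
        ("columnar", (1.2, 1.25, 1.3, 1.3, 1.25, 1.1), (11, 13), 0.10, 0.0),
        ("ellipsoid", (0.1, 1.6, 3.2, 3.2, 1.6, 0.1), (10, 12), 0.25, 0.0),
        ("umbrella", (0.4, 0.8, 1.6, 3.0, 4.0, 3.2), (8, 10), 0.45, 0.15),
        ("weeping", (2.4, 3.5, 2.9, 1.9, 0.9, 0.2), (7, 9), 0.10, 0.35),
        ("tall_thin", (1.5, 0.9, 0.6, 0.4, 0.25, 0.05), (26, 30), 0.20, 0.0),
        ("broad_dome", (2.0, 3.3, 4.0, 3.8, 2.8, 1.0), (12, 14), 0.20, 0.0),
        ("shrub_ball", (1.0, 2.0, 2.5, 2.5, 2.0, 1.0), (4, 5), 0.05, 0.0),
        ("hourglass", (2.6, 1.5, 0.7, 0.7, 1.5, 2.4), (16, 18), 0.10, 0.0),
        ("asym_oak", (2.4, 2.7, 2.9, 3.0, 2.9, 2.5), (15, 17), 0.30, 0.60),
    ]
    return [
        _with_density(
            target,
            species_id=name,
            radius_profile=radii,
            height_range=hr,
            trunk_fraction=tf,
            asymmetry=asym,
            noise_sd=0.05,
        )
        for name, radii, hr, tf, asym in spec
    ]


def _hard7() -> list[SpeciesProfile]:
    # overlapping crown shapes and noisy points: the merging regime
    target = 1500.0
    spec = [
        ("beech", (1.8, 3.0, 3.6, 3.4, 2.4, 0.8), (22, 30), 0.35, 0.30),
        ("douglas_fir", (2.6, 2.2, 1.8, 1.3, 0.8, 0.1), (25, 38), 0.25, 0.15),
        ("oak", (2.0, 3.2, 3.6, 3.2, 2.2, 1.0), (18, 26), 0.30, 0.40),
        ("ash", (1.6, 2.6, 3.1, 3.0, 2.2, 0.9), (20, 28), 0.35, 0.30),
        ("spruce", (2.4, 2.1, 1.7, 1.3, 0.8, 0.1), (20, 32), 0.15, 0.15),
        ("pine", (1.4, 1.9, 2.3, 2.3, 1.8, 0.6), (18, 28), 0.45, 0.25),
        ("red_oak", (1.9, 3.1, 3.5, 3.3, 2.3, 0.9), (20, 28), 0.30, 0.35),
    ]
    return [
        _with_density(
            target,
            species_id=name,
            radius_profile=radii,
            height_range=hr,
            trunk_fraction=tf,
            asymmetry=asym,
            noise_sd=0.15,
        )
        for name, radii, hr, tf, asym in spec
    ]


#: per-species tree counts for the imbalanced hard7 protocol
HARD7_COUNTS = (164, 183, 22, 39, 158, 25, 100)

_PACKS = {"default10": _default10, "hard7": _hard7}


def profile_pack(name: str) -> list[SpeciesProfile]:
    """Return a named profile pack ('default10' or 'hard7')."""
    if name not in _PACKS:
        raise ValidationError(
            f"unknown profile pack {name!r}; available: {sorted(_PACKS)}"
        )
    return _PACKS[name]()


def load_profiles_yaml(path: str | Path) -> list[SpeciesProfile]:
    """Load species profiles from a YAML file (a list of mappings)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError(f"{path}: expected a YAML list of profile mappings")
    profiles = []
    for rec in raw:
        rec = dict(rec)
        rec["radius_profile"] = tuple(rec["radius_profile"])
        rec["height_range"] = tuple(rec["height_range"])
        profiles.append(SpeciesProfile(**rec))
    return profiles
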