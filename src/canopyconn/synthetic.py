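"""Seeded synthetic urban scenes: reflectance pairs plus voxel canopies.

The generator emulates the two inputs the connectivity analysis needs -
a red/NIR reflectance pair (for NDVI) and a 3D fractional-cover voxel
canopy - for a small town-like scene with controllable urban form.
Three archetypes sketch qualitatively different town histories:

* ``planned_green`` - designed greenspace: generous, contiguous greens
  and large tree stands (low fragmentation).
* ``medieval_clustered`` - an organic historical core with intermediate
  green cover and fragmentation.
* ``terraced`` - dense row housing with small private gardens: sparse,
  highly fragmented vegetation.

Vegetation is laid down as seeded random discs ("blob dropping") per
stratum until each target cover fraction is met.  The ``fragmentation``
knob maps to the disc radius scale: 0 gives a few large blobs, 1 gives
many small ones.  Tree crowns and shrubs are horizontally exclusive;
grass may underlie either, and a grass understorey patch is always
seeded beneath a tree stand when both layers are requested, so the
stratification's understorey path is exercised.  Buildings and roads
exist only implicitly: non-vegetated pixels get NDVI < 0.2 and empty
voxel columns.

One RNG stream per scene (``numpy.random.default_rng(seed)``) makes the
output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import ReflectancePair, Stratum, VoxelCanopy

__all__ = ["SceneConfig", "ARCHETYPES", "archetype_params", "generate_scene"]

#: Cover-fraction slack the blob-dropper aims for: generation stops as
#: soon as realized cover reaches the target, and final discs are shrunk
#: adaptively, so realized cover overshoots by at most ~0.02 on grids
#: >= 128 px and converges to the target as the grid grows.
COVER_TOL = 0.03

_STRATA_3D = (Stratum.GRASS, Stratum.SHRUB, Stratum.TREE)

# disc radius multiplier per stratum: tree stands are broad, shrubs are
# garden-scale features
_RADIUS_FACTOR = {Stratum.GRASS: 1.2, Stratum.SHRUB: 0.6, Stratum.TREE: 1.5}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    ``target_cover`` maps each 3D stratum name to its desired fraction
    of the scene footprint.  Shrub and tree columns are exclusive, so
    their targets must sum to at most 1; grass overlaps freely.
    ``fragmentation`` in [0, 1]: 0 = few large blobs, 1 = many small.
    """

    width_px: int = 128
    height_px: int = 128
    pixel_size_m: float = 1.5
    voxel_height_m: float = 0.5
    max_height_m: float = 12.0
    archetype: str = "planned_green"
    target_cover: dict = field(
        default_factory=lambda: {"grass": 0.3, "shrub": 0.06, "tree": 0.18}
    )
    fragmentation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1 or self.width_px * self.height_px < 4:
            raise ValueError("scene needs at least 4 pixels")
        if self.pixel_size_m <= 0 or self.voxel_height_m <= 0:
            raise ValueError("pixel and voxel sizes must be positive")
        if self.max_height_m <= 4.0:
            raise ValueError("max_height_m must exceed 4 m so the tree band is reachable")
        if not (0.0 <= self.fragmentation <= 1.0):
            raise ValueError("fragmentation must lie in [0, 1]")
        cover = {Stratum(k): float(v) for k, v in self.target_cover.items()}
        unknown = set(cover) - set(_STRATA_3D)
        if unknown:
            raise ValueError(f"target_cover keys must be grass/shrub/tree, got {unknown}")
        for stratum in _STRATA_3D:
            cover.setdefault(stratum, 0.0)
        for stratum, frac in cover.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{stratum.value} target cover {frac} outside [0, 1]")
        exclusive = cover[Stratum.SHRUB] + cover[Stratum.TREE]
        if exclusive > 1.0:
            raise ValueError(
                f"impossible targets: shrub + tree covers are horizontally "
                f"exclusive and sum to {exclusive:.2f} > 1"
            )
        object.__setattr__(self, "target_cover", {s.value: cover[s] for s in _STRATA_3D})

    @property
    def n_levels(self) -> int:
        return int(np.ceil(self.max_height_m / self.voxel_height_m))


#: Archetype parameter table (illustrative urban forms, not calibrated
#: to any real town).
ARCHETYPES: dict[str, dict] = {
    "planned_green": dict(
        target_cover={"grass": 0.30, "shrub": 0.06, "tree": 0.18},
        fragmentation=0.20,
    ),
    "medieval_clustered": dict(
        target_cover={"grass": 0.22, "shrub": 0.05, "tree": 0.12},
        fragmentation=0.45,
    ),
    "terraced": dict(
        target_cover={"grass": 0.16, "shrub": 0.04, "tree": 0.07},
        fragmentation=0.70,
    ),
}


def archetype_params(archetype: str, **overrides) -> SceneConfig:
    """A ready-to-run :class:`SceneConfig` for one of the three urban
    form archetypes; keyword overrides replace any field."""
    try:
        params = ARCHETYPES[archetype]
    except KeyError:
        raise ValueError(
            f"unknown archetype {archetype!r}; choose from {sorted(ARCHETYPES)}"
        ) from None
    return replace(SceneConfig(archetype=archetype, **params), **overrides)


def _paint_disc(mask: np.ndarray, row: int, col: int, radius: float) -> None:
    """OR a filled disc into ``mask`` (center distance <= radius), using
    a bounding-box slice so large grids stay cheap."""
    h, w = mask.shape
    r = int(np.ceil(radius))
    r0, r1 = max(0, row - r), min(h, row + r + 1)
    c0, c1 = max(0, col - r), min(w, col + r + 1)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - row) ** 2 + (cc - col) ** 2 <= radius * radius


def _drop_blobs(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target: float,
    mean_radius: float,
    allowed: np.ndarray | None = None,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Drop random discs until the mask covers ``target`` of the grid.

    Discs landing outside ``allowed`` (if given) are clipped to it.  The
    radius of late discs shrinks toward the remaining deficit so the
    final cover overshoots the target as little as disc granularity
    permits.  Stops early if the allowed region saturates.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool) if start is None else start.copy()
    n_total = h * w
    max_attempts = 50 * n_total // max(1, int(np.pi * mean_radius**2)) + 2000
    attempts = 0
    while mask.mean() < target and attempts < max_attempts:
        attempts += 1
        row = int(rng.integers(h))
        col = int(rng.integers(w))
        radius = float(rng.uniform(0.6, 1.4)) * mean_radius
        remaining_px = (target - mask.mean()) * n_total
        if np.pi * radius**2 > 2.0 * remaining_px:
            radius = max(1.0, float(np.sqrt(2.0 * remaining_px / np.pi)))
        blob = np.zeros(shape, dtype=bool)
        _paint_disc(blob, row, col, radius)
        if allowed is not None:
            blob &= allowed
        mask |= blob
        if allowed is not None and not (allowed & ~mask).any():
            break
    return mask


def _radius_scale(config: SceneConfig) -> float:
    """Mean disc radius (px) implied by the fragmentation knob."""
    r_min = 1.2
    r_cap = max(1.5, min(config.height_px, config.width_px) / 8.0)
    return r_min + (1.0 - config.fragmentation) ** 1.5 * (r_cap - r_min)


def _layer_masks(config: SceneConfig, rng: np.random.Generator) -> dict[Stratum, np.ndarray]:
    shape = (config.height_px, config.width_px)
    base_r = _radius_scale(config)
    cover = {Stratum(k): v for k, v in config.target_cover.items()}

    tree = _drop_blobs(rng, shape, cover[Stratum.TREE], base_r * _RADIUS_FACTOR[Stratum.TREE])
    shrub = _drop_blobs(
        rng, shape, cover[Stratum.SHRUB], base_r * _RADIUS_FACTOR[Stratum.SHRUB], allowed=~tree
    )

    grass_r = base_r * _RADIUS_FACTOR[Stratum.GRASS]
    start = None
    if cover[Stratum.GRASS] > 0 and tree.any():
        # guarantee an understorey: seed one grass patch on a tree stand
        tree_rows, tree_cols = np.nonzero(tree)
        i = int(rng.integers(tree_rows.size))
        start = np.zeros(shape, dtype=bool)
        _paint_disc(start, int(tree_rows[i]), int(tree_cols[i]), max(1.0, 0.8 * grass_r))
    grass = _drop_blobs(rng, shape, cover[Stratum.GRASS], grass_r, start=start)

    return {Stratum.GRASS: grass, Stratum.SHRUB: shrub, Stratum.TREE: tree}


def _build_canopy(
    config: SceneConfig, rng: np.random.Generator, masks: dict[Stratum, np.ndarray]
) -> VoxelCanopy:
    shape = (config.height_px, config.width_px)
    n_levels = config.n_levels
    dz = config.voxel_height_m
    centers = (np.arange(n_levels) + 0.5) * dz
    cover = np.zeros(shape + (n_levels,))

    grass_levels = np.flatnonzero(centers < 0.5)
    shrub_levels = np.flatnonzero((centers >= 0.5) & (centers <= 4.0))
    tree_levels = np.flatnonzero(centers > 4.0)

    grass = masks[Stratum.GRASS]
    if grass.any() and grass_levels.size:
        for lvl in grass_levels:
            cover[grass, lvl] = rng.uniform(0.2, 0.9, int(grass.sum()))

    shrub = masks[Stratum.SHRUB]
    if shrub.any() and shrub_levels.size:
        # per-column shrub top height in [1, 4] m
        tops = rng.uniform(1.0, 4.0, int(shrub.sum()))
        for lvl in shrub_levels:
            occupied = tops >= centers[lvl]
            vals = np.where(occupied, rng.uniform(0.2, 0.8, tops.size), 0.0)
            cover[shrub, lvl] = vals

    tree = masks[Stratum.TREE]
    if tree.any():
        if not tree_levels.size:
            raise ValueError("max_height_m too small to host a tree crown voxel")
        # crown from the first above-4 m level up to a per-column top
        tops = rng.uniform(centers[tree_levels[0]], n_levels * dz, int(tree.sum()))
        for lvl in tree_levels:
            occupied = tops >= centers[lvl]
            vals = np.where(occupied, rng.uniform(0.3, 0.95, tops.size), 0.0)
            cover[tree, lvl] = vals

    return VoxelCanopy(cover, config.pixel_size_m, dz, base_height_m=0.0)


def _build_reflectance(
    config: SceneConfig, rng: np.random.Generator, vegetated: np.ndarray
) -> ReflectancePair:
    """Back-solve red reflectance from a drawn NDVI with NIR pinned at 0.5.

    Vegetated pixels draw NDVI uniformly in [0.4, 0.9], everything else
    in [-0.2, 0.1], so the 0.2 vegetation threshold separates the two
    populations cleanly while still exercising the NDVI arithmetic.
    """
    shape = vegetated.shape
    ndvi = np.where(
        vegetated,
        rng.uniform(0.4, 0.9, shape),
        rng.uniform(-0.2, 0.1, shape),
    )
    nir = np.full(shape, 0.5)
    red = nir * (1.0 - ndvi) / (1.0 + ndvi)
    return ReflectancePair(red=red, nir=nir, pixel_size_m=config.pixel_size_m)


def generate_scene(config: SceneConfig) -> tuple[ReflectancePair, VoxelCanopy]:
    """Generate one synthetic scene; bit-deterministic for a fixed config.

    Returns the reflectance pair (NDVI route) and the voxel canopy
    (volumetric route) on the same horizontal grid, ready for
    :func:`canopyconn.stratify.stratify_scene`.
    """
    rng = np.random.default_rng(config.seed)
    masks = _layer_masks(config, rng)
    canopy = _build_canopy(config, rng, masks)
    vegetated = masks[Stratum.GRASS] | masks[Stratum.SHRUB] | masks[Stratum.TREE]
    pair = _build_reflectance(config, rng, vegetated)
    return pair, canopy
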