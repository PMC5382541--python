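"""Stratification: from reflectance and voxel canopy to binary layer masks.

The optical route thresholds NDVI to get the flat 2D green-cover mask.
The volumetric route thresholds fractional voxel cover, assigns each
occupied voxel to a height band (grass < 0.5 m, shrub 0.5-4 m,
tree > 4 m by voxel-center height) and projects each band onto the
ground.  The NDVI mask gates all three strata, so non-vegetated columns
never contribute, and a single column may carry several strata (e.g.
grass beneath a tree crown - the understorey).
"""

from __future__ import annotations

import numpy as np

from .grids import (
    NdviGrid,
    ReflectancePair,
    StrataThresholds,
    Stratum,
    StratumMask,
    VoxelCanopy,
)

__all__ = [
    "compute_ndvi",
    "vegetation_mask",
    "voxel_presence",
    "project_strata",
    "stratify_scene",
]

#: NDVI value emitted where red + nir = 0 (no signal -> non-vegetated).
NDVI_FILL = 0.0


def compute_ndvi(pair: ReflectancePair) -> NdviGrid:
    """NDVI = (nir - red) / (nir + red), elementwise.

    Pixels where both bands are zero carry no information and receive
    :data:`NDVI_FILL` (0.0), which falls below the vegetation threshold.
    """
    red, nir = pair.red, pair.nir
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), NDVI_FILL)
    return NdviGrid(ndvi, pair.pixel_size_m)


def vegetation_mask(ndvi: NdviGrid, thresholds: StrataThresholds | None = None) -> StratumMask:
    """Flat 2D green-cover mask: pixel vegetated iff NDVI >= ndvi_min (inclusive)."""
    thresholds = thresholds or StrataThresholds()
    return StratumMask(ndvi.values >= thresholds.ndvi_min, Stratum.GREEN2D, ndvi.pixel_size_m)


def voxel_presence(canopy: VoxelCanopy, thresholds: StrataThresholds | None = None) -> np.ndarray:
    """Occupancy grid: voxel vegetated iff fractional cover >= cover_min (inclusive)."""
    thresholds = thresholds or StrataThresholds()
    return canopy.cover >= thresholds.cover_min


def _band_levels(canopy: VoxelCanopy, thresholds: StrataThresholds) -> dict[Stratum, np.ndarray]:
    """Level indices per height band, by voxel-center height.

    Bands: grass center < grass_max_h; shrub grass_max_h <= center <=
    shrub_max_h (closed); tree center > shrub_max_h.  Every level falls
    in exactly one band.
    """
    centers = canopy.level_center_heights()
    return {
        Stratum.GRASS: np.flatnonzero(centers < thresholds.grass_max_h),
        Stratum.SHRUB: np.flatnonzero(
            (centers >= thresholds.grass_max_h) & (centers <= thresholds.shrub_max_h)
        ),
        Stratum.TREE: np.flatnonzero(centers > thresholds.shrub_max_h),
    }


def project_strata(
    presence: np.ndarray,
    green2d: StratumMask,
    canopy: VoxelCanopy,
    thresholds: StrataThresholds | None = None,
) -> tuple[StratumMask, StratumMask, StratumMask]:
    """Project the occupancy grid to per-stratum ground masks.

    A column belongs to a stratum iff it is vegetated in the 2D NDVI
    mask *and* at least one occupied voxel's center height falls in the
    stratum's band.  Columns can belong to several strata, which is how
    understorey (grass under canopy) is represented.

    Returns ``(grass, shrub, tree)`` masks.
    """
    thresholds = thresholds or StrataThresholds()
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != canopy.shape:
        raise ValueError(
            f"presence shape {presence.shape} does not match canopy {canopy.shape}"
        )
    if presence.shape[:2] != green2d.shape:
        raise ValueError(
            f"horizontal geometry mismatch: canopy {presence.shape[:2]} vs "
            f"green2d {green2d.shape}"
        )
    bands = _band_levels(canopy, thresholds)
    out = []
    for stratum in (Stratum.GRASS, Stratum.SHRUB, Stratum.TREE):
        levels = bands[stratum]
        if levels.size:
            hit = presence[:, :, levels].any(axis=2)
        else:
            hit = np.zeros(green2d.shape, dtype=bool)
        out.append(StratumMask(hit & green2d.values, stratum, green2d.pixel_size_m))
    return tuple(out)


def stratify_scene(
    pair: ReflectancePair,
    canopy: VoxelCanopy,
    thresholds: StrataThresholds | None = None,
) -> dict[Stratum, StratumMask]:
    """Full stratification: reflectance + canopy -> the four layer masks."""
    thresholds = thresholds or StrataThresholds()
    ndvi = compute_ndvi(pair)
    green2d = vegetation_mask(ndvi, thresholds)
    presence = voxel_presence(canopy, thresholds)
    grass, shrub, tree = project_strata(presence, green2d, canopy, thresholds)
    return {
        Stratum.GREEN2D: green2d,
        Stratum.GRASS: grass,
        Stratum.SHRUB: shrub,
        Stratum.TREE: tree,
    }
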