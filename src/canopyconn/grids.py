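"""Core raster and voxel containers shared across the pipeline.

All grids are row-major numpy arrays with the origin at the top-left
corner; the center of pixel (row, col) sits at ((col + 0.5), (row + 0.5))
times ``pixel_size_m``.  A voxel canopy adds a vertical axis: level ``k``
spans heights ``[base + k*dz, base + (k+1)*dz)`` above ground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Stratum",
    "ReflectancePair",
    "NdviGrid",
    "StratumMask",
    "VoxelCanopy",
    "StrataThresholds",
]


class Stratum(str, Enum):
    """Vegetation layer identity.

    ``GREEN2D`` is the flat optical view (any vegetation, from NDVI);
    the other three are vertical strata resolved from the voxel canopy.
    """

    GREEN2D = "green2d"
    GRASS = "grass"
    SHRUB = "shrub"
    TREE = "tree"


def _require_2d(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2D array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ReflectancePair:
    """Mean red and near-infrared reflectance grids, values in [0, 1]."""

    red: np.ndarray
    nir: np.ndarray
    pixel_size_m: float = 1.5

    def __post_init__(self) -> None:
        red = _require_2d(self.red, "red").astype(float)
        nir = _require_2d(self.nir, "nir").astype(float)
        if red.shape != nir.shape:
            raise ValueError(
                f"red and nir shapes differ: {red.shape} vs {nir.shape}"
            )
        for name, band in (("red", red), ("nir", nir)):
            if not np.all(np.isfinite(band)):
                raise ValueError(f"{name} reflectance contains non-finite values")
            if band.min() < 0.0 or band.max() > 1.0:
                raise ValueError(f"{name} reflectance must lie in [0, 1]")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        object.__setattr__(self, "red", red)
        object.__setattr__(self, "nir", nir)

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass(frozen=True)
class NdviGrid:
    """Normalized Difference Vegetation Index, (NIR - red)/(NIR + red)."""

    values: np.ndarray
    pixel_size_m: float = 1.5

    def __post_init__(self) -> None:
        values = _require_2d(self.values, "values").astype(float)
        if not np.all(np.isfinite(values)):
            raise ValueError("NDVI contains non-finite values")
        if values.min() < -1.0 or values.max() > 1.0:
            raise ValueError("NDVI must lie in [-1, 1]")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class StratumMask:
    """Binary presence raster for one vegetation layer."""

    values: np.ndarray
    stratum: Stratum
    pixel_size_m: float = 1.5

    def __post_init__(self) -> None:
        values = _require_2d(self.values, "values")
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be boolean (0/1)")
            values = values.astype(bool)
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "stratum", Stratum(self.stratum))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size_m ** 2

    def with_values(self, values: np.ndarray) -> "StratumMask":
        return StratumMask(values, self.stratum, self.pixel_size_m)


@dataclass(frozen=True)
class VoxelCanopy:
    """3D fractional vegetation cover, shape (rows, cols, levels).

    Level ``k`` occupies heights ``[base_height_m + k*voxel_height_m,
    base_height_m + (k+1)*voxel_height_m)`` above ground.
    """

    cover: np.ndarray
    pixel_size_m: float = 1.5
    voxel_height_m: float = 0.5
    base_height_m: float = 0.0

    def __post_init__(self) -> None:
        cover = np.asarray(self.cover, dtype=float)
        if cover.ndim != 3:
            raise ValueError(f"cover must be 3D (rows, cols, levels), got {cover.shape}")
        if not np.all(np.isfinite(cover)):
            raise ValueError("cover contains non-finite values")
        if cover.min() < 0.0 or cover.max() > 1.0:
            raise ValueError("fractional cover must lie in [0, 1]")
        if self.pixel_size_m <= 0 or self.voxel_height_m <= 0:
            raise ValueError("pixel_size_m and voxel_height_m must be positive")
        object.__setattr__(self, "cover", cover)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cover.shape

    @property
    def n_levels(self) -> int:
        return self.cover.shape[2]

    def level_center_heights(self) -> np.ndarray:
        """Above-ground height of each level's vertical midpoint, in metres."""
        k = np.arange(self.n_levels)
        return self.base_height_m + (k + 0.5) * self.voxel_height_m


@dataclass(frozen=True)
class StrataThresholds:
    """Thresholds that define vegetation presence and the vertical bands.

    Defaults follow the standard urban-greenspace convention: a pixel is
    vegetated at NDVI >= 0.2; a voxel is occupied at >= 1% fractional
    cover; grass is vegetation below 0.5 m, shrubs between 0.5 and 4 m,
    trees above 4 m.
    """

    ndvi_min: float = 0.2
    cover_min: float = 0.01
    grass_max_h: float = 0.5
    shrub_max_h: float = 4.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ndvi_min <= 1.0):
            raise ValueError("ndvi_min must lie in [-1, 1]")
        if not (0.0 < self.cover_min < 1.0):
            raise ValueError("cover_min must lie in (0, 1)")
        if not (0.0 < self.grass_max_h < self.shrub_max_h):
            raise ValueError("need 0 < grass_max_h < shrub_max_h")
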