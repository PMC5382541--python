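"""Patch structure and structural connectivity metrics.

A patch is a maximal connected component of a binary layer mask under a
chosen pixel neighborhood (8-connected by default, 4-connected
available).  From the patch areas ``a_ij`` and the total landscape area
``A`` (the full raster extent, vegetated or not) four landscape metrics
are derived:

* landscape proportion, ``sum(a_ij) / A``;
* small patch density, the number of patches smaller than 30 m**2 per
  hectare of landscape - a fragmentation indicator sensitive to garden-
  scale green features;
* largest patch index (LPI), ``100 * max(a_ij) / A`` percent;
* connectivity index (CI), the landscape division index
  ``1 - sum((a_ij / A)**2)``: the probability that two pixels drawn
  uniformly at random from the landscape do not lie in the same patch.
  Higher CI means lower connectivity; an empty landscape has CI = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import StratumMask

__all__ = [
    "PatchLabeling",
    "StructuralMetrics",
    "label_patches",
    "landscape_proportion",
    "small_patch_density",
    "largest_patch_index",
    "connectivity_index",
    "structural_summary",
    "SMALL_PATCH_MAX_AREA_M2",
]

#: Patches strictly below this area count toward small-patch density.
SMALL_PATCH_MAX_AREA_M2 = 30.0

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class PatchLabeling:
    """Connected-component labeling of one layer mask.

    ``labels`` holds 0 for background and dense ids 1..n ordered by each
    patch's first pixel in row-major scan order.  ``patch_areas_m2`` is
    indexed by ``label - 1``.
    """

    labels: np.ndarray
    patch_areas_m2: np.ndarray
    landscape_area_m2: float
    neighborhood: int
    pixel_size_m: float

    @property
    def n_patches(self) -> int:
        return len(self.patch_areas_m2)


def label_patches(mask: StratumMask, neighborhood: int = 8) -> PatchLabeling:
    """Label maximal connected components of a layer mask.

    Labels are renumbered so patch 1 is the one whose first pixel comes
    earliest in row-major order, making the labeling deterministic and
    independent of the underlying labeling algorithm.
    """
    if neighborhood not in _STRUCTURES:
        raise ValueError(f"neighborhood must be 4 or 8, got {neighborhood}")
    raw, n = ndimage.label(mask.values, structure=_STRUCTURES[neighborhood])
    if n:
        flat = raw.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        # reversed so earlier indices overwrite later ones
        first[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[raw]
        counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    else:
        labels = raw
        counts = np.zeros(0, dtype=np.int64)
    pixel_area = mask.pixel_area_m2
    return PatchLabeling(
        labels=labels,
        patch_areas_m2=counts.astype(float) * pixel_area,
        landscape_area_m2=float(mask.values.size) * pixel_area,
        neighborhood=neighborhood,
        pixel_size_m=mask.pixel_size_m,
    )


def landscape_proportion(labeling: PatchLabeling) -> float:
    """Fraction of the landscape covered by vegetation, sum(a_ij)/A."""
    return float(labeling.patch_areas_m2.sum() / labeling.landscape_area_m2)


def small_patch_density(
    labeling: PatchLabeling, max_area_m2: float = SMALL_PATCH_MAX_AREA_M2
) -> float:
    """Patches with area strictly below ``max_area_m2``, per hectare."""
    n_small = int((labeling.patch_areas_m2 < max_area_m2).sum())
    hectares = labeling.landscape_area_m2 / 10_000.0
    return n_small / hectares


def largest_patch_index(labeling: PatchLabeling) -> float:
    """Percent of the landscape occupied by the largest patch (0 if empty)."""
    if labeling.n_patches == 0:
        return 0.0
    return float(100.0 * labeling.patch_areas_m2.max() / labeling.landscape_area_m2)


def connectivity_index(labeling: PatchLabeling) -> float:
    """Landscape division index CI = 1 - sum((a_ij/A)**2).

    The probability that two pixels drawn uniformly (with replacement)
    from the whole landscape are not in the same patch; background
    pixels never share a patch.  Empty landscape -> 1.0; a single patch
    covering everything -> 0.0.
    """
    frac = labeling.patch_areas_m2 / labeling.landscape_area_m2
    return float(1.0 - np.sum(frac * frac))


@dataclass(frozen=True)
class StructuralMetrics:
    """The four per-layer structural connectivity metrics."""

    landscape_proportion: float
    small_patch_density: float  # patches < 30 m^2 per hectare
    largest_patch_index: float  # percent
    ci: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.landscape_proportion <= 1.0):
            raise ValueError("landscape_proportion must lie in [0, 1]")
        if not (0.0 <= self.ci <= 1.0 + 1e-12):
            raise ValueError("ci must lie in [0, 1]")
        # the largest patch alone already bounds the division index
        if self.ci > 1.0 - (self.largest_patch_index / 100.0) ** 2 + 1e-9:
            raise ValueError("ci inconsistent with largest patch index")


def structural_summary(mask: StratumMask, neighborhood: int = 8) -> StructuralMetrics:
    """All four structural metrics from a single labeling pass."""
    labeling = label_patches(mask, neighborhood)
    return StructuralMetrics(
        landscape_proportion=landscape_proportion(labeling),
        small_patch_density=small_patch_density(labeling),
        largest_patch_index=largest_patch_index(labeling),
        ci=connectivity_index(labeling),
    )
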