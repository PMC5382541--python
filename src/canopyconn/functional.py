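"""Functional connectivity: CI as a function of dispersal distance.

Buffering a vegetation layer outward by a distance ``d`` merges patches
that an organism with dispersal capacity ``d`` can move between; the
connectivity index of the buffered mask is therefore a functional (not
purely structural) connectivity measure.  Sweeping ``d`` in 1 m steps
until the buffered layer covers the landscape yields a monotone
non-increasing CI-vs-distance curve.  Comparing a stratum's curve
against the flat 2D green-cover curve gives the bias introduced by
ignoring vertical structure: since each stratum mask is a subset of the
2D mask, the stratum CI can never fall below the 2D CI at any distance.

Buffers are isotropic Euclidean expansions measured between pixel
centers (threshold inclusive) and ignore built barriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import StratumMask, Stratum
from .patches import connectivity_index, label_patches

__all__ = [
    "ConnectivityCurve",
    "BiasCurve",
    "buffer_mask",
    "functional_curve",
    "threshold_distance",
    "bias_curve",
    "peak_bias",
    "CI_THRESHOLD_DEFAULT",
]

#: CI below this marks "high connectivity" (>85% chance two random
#: pixels are connected).
CI_THRESHOLD_DEFAULT = 0.15

# absorbs floating-point noise at exact buffer radii (e.g. d == 2 px)
_DIST_EPS = 1e-9


@dataclass(frozen=True)
class ConnectivityCurve:
    """CI sampled at increasing buffer distances for one layer.

    ``terminated_full_cover`` is True when the sweep reached a buffered
    mask covering the whole landscape (CI exactly 0).
    """

    layer: Stratum
    distances_m: np.ndarray
    ci_values: np.ndarray
    terminated_full_cover: bool

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_m, dtype=float)
        ci = np.asarray(self.ci_values, dtype=float)
        if d.shape != ci.shape or d.ndim != 1 or d.size == 0:
            raise ValueError("distances and ci_values must be equal-length 1D arrays")
        if d[0] != 0.0:
            raise ValueError("curve must start at distance 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(np.diff(ci) > 1e-12):
            raise ValueError("ci_values must be non-increasing")
        if self.terminated_full_cover != (ci[-1] == 0.0):
            raise ValueError("terminated_full_cover inconsistent with final CI")
        object.__setattr__(self, "distances_m", d)
        object.__setattr__(self, "ci_values", ci)

    def __len__(self) -> int:
        return self.distances_m.size


@dataclass(frozen=True)
class BiasCurve:
    """CI difference of one stratum relative to the 2D green cover.

    ``delta_ci(d) = CI_stratum(d) - CI_green2d(d)``; non-negative
    whenever the stratum mask is contained in the 2D mask.
    """

    layer: Stratum
    distances_m: np.ndarray
    delta_ci: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_m, dtype=float)
        delta = np.asarray(self.delta_ci, dtype=float)
        if d.shape != delta.shape or d.ndim != 1:
            raise ValueError("distances and delta_ci must be equal-length 1D arrays")
        object.__setattr__(self, "distances_m", d)
        object.__setattr__(self, "delta_ci", delta)


def _center_distances_m(mask: StratumMask) -> np.ndarray:
    """Euclidean distance (m) from every pixel center to the nearest
    vegetated pixel center, computed exactly via the feature transform."""
    values = mask.values
    if not values.any():
        raise ValueError("mask has no vegetated pixels")
    if values.all():
        return np.zeros(values.shape)
    nearest = ndimage.distance_transform_edt(~values, return_distances=False, return_indices=True)
    rows, cols = np.indices(values.shape)
    dr = rows - nearest[0]
    dc = cols - nearest[1]
    # exact integer squared pixel distance, then scale once
    d2 = dr.astype(np.int64) ** 2 + dc.astype(np.int64) ** 2
    return np.sqrt(d2.astype(float)) * mask.pixel_size_m


def buffer_mask(mask: StratumMask, distance_m: float) -> StratumMask:
    """Expand the mask to all pixels whose center lies within
    ``distance_m`` (inclusive) of a vegetated pixel center."""
    if distance_m < 0:
        raise ValueError("distance_m must be non-negative")
    if distance_m == 0 or not mask.values.any() or mask.values.all():
        return mask
    dist = _center_distances_m(mask)
    return mask.with_values(dist <= distance_m + _DIST_EPS)


def functional_curve(
    mask: StratumMask,
    step_m: float = 1.0,
    neighborhood: int = 8,
    max_distance_m: float | None = None,
) -> ConnectivityCurve:
    """CI of the buffered layer at d = 0, step, 2*step, ...

    The sweep stops at the first distance where the buffered mask covers
    the whole landscape (CI = 0), or at ``max_distance_m`` (default: the
    grid diagonal, which guarantees termination).  The first value
    equals the structural CI of the unbuffered layer.
    """
    if step_m <= 0:
        raise ValueError("step_m must be positive")
    if not mask.values.any():
        raise ValueError("functional curve undefined for an empty mask")
    nrows, ncols = mask.shape
    diagonal = float(np.hypot(nrows, ncols)) * mask.pixel_size_m
    if max_distance_m is None:
        max_distance_m = diagonal
    dist = _center_distances_m(mask)

    distances: list[float] = []
    ci_values: list[float] = []
    full_cover = False
    d = 0.0
    k = 0
    while True:
        buffered = mask.with_values(dist <= d + _DIST_EPS)
        ci = connectivity_index(label_patches(buffered, neighborhood))
        distances.append(d)
        ci_values.append(ci)
        if buffered.values.all():
            full_cover = True
            break
        if d >= max_distance_m:
            break
        k += 1
        d = min(k * step_m, max_distance_m)
    if not full_cover:
        warnings.warn(
            f"functional curve for {mask.stratum.value} stopped at "
            f"{distances[-1]:.1f} m without reaching full cover",
            stacklevel=2,
        )
    return ConnectivityCurve(
        layer=mask.stratum,
        distances_m=np.array(distances),
        ci_values=np.array(ci_values),
        terminated_full_cover=full_cover,
    )


def threshold_distance(
    curve: ConnectivityCurve, ci_threshold: float = CI_THRESHOLD_DEFAULT
) -> float | None:
    """Smallest sampled distance with CI strictly below the threshold,
    or None if the curve never attains it."""
    below = np.flatnonzero(curve.ci_values < ci_threshold)
    if below.size == 0:
        return None
    return float(curve.distances_m[below[0]])


def bias_curve(
    stratum_curve: ConnectivityCurve, green2d_curve: ConnectivityCurve
) -> BiasCurve:
    """Pointwise CI difference, stratum minus 2D green cover.

    The curves must share the sampling step; the shorter one (already at
    full cover) is extended with trailing zeros.
    """
    n = min(len(stratum_curve), len(green2d_curve))
    if n > 1 and not np.allclose(
        stratum_curve.distances_m[:n], green2d_curve.distances_m[:n]
    ):
        raise ValueError("curves are sampled on different distance steps")
    for curve, name in ((stratum_curve, "stratum"), (green2d_curve, "green2d")):
        if len(curve) < max(len(stratum_curve), len(green2d_curve)) and not curve.terminated_full_cover:
            raise ValueError(f"shorter {name} curve did not reach full cover; cannot extend")
    longer = stratum_curve if len(stratum_curve) >= len(green2d_curve) else green2d_curve
    m = len(longer)

    def extended(curve: ConnectivityCurve) -> np.ndarray:
        return np.pad(curve.ci_values, (0, m - len(curve)))

    return BiasCurve(
        layer=stratum_curve.layer,
        distances_m=longer.distances_m.copy(),
        delta_ci=extended(stratum_curve) - extended(green2d_curve),
    )


def peak_bias(bias: BiasCurve) -> tuple[float, float]:
    """Distance and value of the maximum CI difference (ties -> smallest
    distance)."""
    if bias.distances_m.size == 0:
        raise ValueError("empty bias curve")
    i = int(np.argmax(bias.delta_ci))  # argmax takes the first maximum
    return float(bias.distances_m[i]), float(bias.delta_ci[i])
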