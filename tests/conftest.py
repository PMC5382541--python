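"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths:
CI is cross-checked by Monte-Carlo pixel-pair sampling, and buffering by
brute-force all-pairs center distances.
"""

from __future__ import annotations

import numpy as np
import pytest

from canopyconn import Stratum, StratumMask


def random_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float = 0.3,
    pixel_size_m: float = 1.5,
    stratum: Stratum = Stratum.GREEN2D,
) -> StratumMask:
    return StratumMask(rng.random(shape) < density, stratum, pixel_size_m)


def mc_ci_estimate(
    labels: np.ndarray, rng: np.random.Generator, n_pairs: int = 100_000
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(two uniform random pixels are NOT in the
    same patch), with its standard error.

    Pixels are drawn with replacement from the whole landscape;
    background pixels (label 0) never share a patch with anything.
    """
    flat = labels.ravel()
    a = flat[rng.integers(flat.size, size=n_pairs)]
    b = flat[rng.integers(flat.size, size=n_pairs)]
    same = (a == b) & (a > 0)
    p_not_same = 1.0 - same.mean()
    se = np.sqrt(p_not_same * (1.0 - p_not_same) / n_pairs)
    return float(p_not_same), float(se)


def brute_force_buffer(mask: StratumMask, distance_m: float) -> np.ndarray:
    """Pixel included iff its center lies within distance_m of any
    vegetated pixel center, by exhaustive all-pairs comparison."""
    values = mask.values
    rows, cols = np.nonzero(values)
    if rows.size == 0:
        return values.copy()
    rr, cc = np.indices(values.shape)
    # (pixels, sources) squared distances in integer pixel units
    d2 = (
        (rr.ravel()[:, None] - rows[None, :]) ** 2
        + (cc.ravel()[:, None] - cols[None, :]) ** 2
    )
    min_d2 = d2.min(axis=1).reshape(values.shape)
    return np.sqrt(min_d2.astype(float)) * mask.pixel_size_m <= distance_m + 1e-9


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
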