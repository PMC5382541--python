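"""File formats: rasters, voxel canopies, curves and configs.

Two raster containers are supported and chosen by file extension:

* ``.asc`` - ESRI ASCII grid, dependency-free and diffable; used for
  small fixtures.  Layer identity travels in the filename suffix
  (``_green2d`` / ``_grass`` / ``_shrub`` / ``_tree``).
* ``.tif``/``.tiff`` - TIFF written with :mod:`tifffile`; grid geometry
  and layer identity are stored as a JSON document in the TIFF image
  description tag.  A voxel canopy is a multi-page TIFF, one page per
  vertical level, bottom first.

Curves and metrics are tidy CSV; scene/run configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .functional import BiasCurve, ConnectivityCurve
from .grids import Stratum, StratumMask, VoxelCanopy
from .patches import StructuralMetrics

__all__ = [
    "read_mask",
    "write_mask",
    "read_canopy",
    "write_canopy",
    "read_curve",
    "write_curve",
    "write_bias_curves",
    "write_metrics",
    "read_scene_config",
    "write_scene_config",
]

_NODATA = -9999


# ---------------------------------------------------------------- masks

def _stratum_from_name(path: Path) -> Stratum:
    for stratum in Stratum:
        if path.stem.endswith(f"_{stratum.value}"):
            return stratum
    raise ValueError(
        f"cannot infer layer from filename {path.name!r}; pass stratum= explicitly"
    )


def _write_ascii_grid(path: Path, values: np.ndarray, cellsize: float) -> None:
    nrows, ncols = values.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cellsize!r}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values.astype(int), fmt="%d")


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float]:
    header: dict[str, str] = {}
    with open(path) as fh:
        for _ in range(6):
            key, _, value = fh.readline().partition(" ")
            header[key.strip().lower()] = value.strip()
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if values.shape != expected:
        raise ValueError(f"{path}: grid shape {values.shape} != header {expected}")
    return values, float(header["cellsize"])


def write_mask(path: str | Path, mask: StratumMask) -> Path:
    path = Path(path)
    if path.suffix == ".asc":
        _write_ascii_grid(path, mask.values, mask.pixel_size_m)
    elif path.suffix in (".tif", ".tiff"):
        meta = {"pixel_size_m": mask.pixel_size_m, "stratum": mask.stratum.value}
        tifffile.imwrite(path, mask.values.astype(np.uint8), description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported mask format: {path.suffix!r}")
    return path


def read_mask(path: str | Path, stratum: Stratum | str | None = None) -> StratumMask:
    path = Path(path)
    if path.suffix == ".asc":
        values, cellsize = _read_ascii_grid(path)
        stratum = Stratum(stratum) if stratum else _stratum_from_name(path)
        return StratumMask(values != 0, stratum, cellsize)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            meta = json.loads(tif.pages[0].description)
        stratum = Stratum(stratum) if stratum else Stratum(meta["stratum"])
        return StratumMask(values != 0, stratum, float(meta["pixel_size_m"]))
    raise ValueError(f"unsupported mask format: {path.suffix!r}")


# --------------------------------------------------------------- canopy

def write_canopy(path: str | Path, canopy: VoxelCanopy) -> Path:
    """Multi-page TIFF (float32, one page per level, bottom level first)."""
    path = Path(path)
    if path.suffix not in (".tif", ".tiff"):
        raise ValueError("canopy is written as multi-page TIFF (.tif)")
    meta = {
        "pixel_size_m": canopy.pixel_size_m,
        "voxel_height_m": canopy.voxel_height_m,
        "base_height_m": canopy.base_height_m,
    }
    pages = np.moveaxis(canopy.cover.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, description=json.dumps(meta))
    return path


def read_canopy(path: str | Path) -> VoxelCanopy:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    if pages.ndim == 2:
        pages = pages[None]
    return VoxelCanopy(
        np.moveaxis(pages.astype(float), 0, 2),
        pixel_size_m=float(meta["pixel_size_m"]),
        voxel_height_m=float(meta["voxel_height_m"]),
        base_height_m=float(meta["base_height_m"]),
    )


# --------------------------------------------------------------- curves

def write_curve(path: str | Path, curve: ConnectivityCurve) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "layer": curve.layer.value,
            "distance_m": curve.distances_m,
            "ci": curve.ci_values,
        }
    ).to_csv(path, index=False)
    return path


def read_curve(path: str | Path) -> ConnectivityCurve:
    df = pd.read_csv(path)
    missing = {"layer", "distance_m", "ci"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: curve CSV missing columns {sorted(missing)}")
    layers = df["layer"].unique()
    if len(layers) != 1:
        raise ValueError(f"{path}: expected a single layer, found {list(layers)}")
    d = df["distance_m"].to_numpy(float)
    if d.size and np.any(np.diff(d) <= 0):
        raise ValueError(f"{path}: distances must be strictly increasing")
    ci = df["ci"].to_numpy(float)
    return ConnectivityCurve(
        layer=Stratum(layers[0]),
        distances_m=d,
        ci_values=ci,
        terminated_full_cover=bool(ci.size and ci[-1] == 0.0),
    )


def write_bias_curves(path: str | Path, biases: list[BiasCurve]) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"layer": b.layer.value, "distance_m": b.distances_m, "delta_ci": b.delta_ci}
        )
        for b in biases
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_metrics(path: str | Path, metrics: dict[Stratum, StructuralMetrics]) -> Path:
    """Tidy CSV: one row per layer with the four structural metrics."""
    path = Path(path)
    rows = [
        {
            "layer": stratum.value,
            "landscape_proportion": m.landscape_proportion,
            "small_patch_density_per_ha": m.small_patch_density,
            "lpi_percent": m.largest_patch_index,
            "ci": m.ci,
        }
        for stratum, m in metrics.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# -------------------------------------------------------------- configs

def write_scene_config(path: str | Path, config) -> Path:
    from dataclasses import asdict

    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    return path


def read_scene_config(path: str | Path):
    from .synthetic import SceneConfig

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SceneConfig(**data)
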