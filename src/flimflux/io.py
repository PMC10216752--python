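"""Readers/writers for the on-disk container formats.

DecayCube: multi-page TIFF (one page per time bin, 16-bit counts) plus a
sidecar JSON with {n_bins, bin_width_ps, rep_period_ps, seed}. Maps: single-
page TIFF. Tables: CSV with unit-suffixed column names (``*_ps``, ``*_frac``,
``*_pct``, ``*_mM``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import Scene
from .tcspc import DecayCube, FitMap

__all__ = [
    "write_decay_cube",
    "read_decay_cube",
    "write_map",
    "read_map",
    "write_scene",
    "write_fitmap",
]


def write_decay_cube(cube: DecayCube, tiff_path, json_path=None, seed: int | None = None) -> None:
    tiff_path = Path(tiff_path)
    json_path = Path(json_path) if json_path else tiff_path.with_suffix(".json")
    pages = np.moveaxis(cube.counts, 2, 0).astype(np.uint16)  # (bin, y, x)
    tifffile.imwrite(tiff_path, pages)
    meta = {
        "n_bins": int(cube.n_bins),
        "bin_width_ps": float(cube.bin_width),
        "rep_period_ps": float(cube.rep_period),
        "seed": seed,
        "provenance": cube.provenance,
    }
    json_path.write_text(json.dumps(meta, indent=2))


def read_decay_cube(tiff_path, json_path=None) -> DecayCube:
    tiff_path = Path(tiff_path)
    json_path = Path(json_path) if json_path else tiff_path.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(f"sidecar metadata not found: {json_path}")
    meta = json.loads(json_path.read_text())
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:  # single-bin cube
        pages = pages[None, ...]
    if pages.shape[0] != meta["n_bins"]:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but metadata declares n_bins = {meta['n_bins']}"
        )
    return DecayCube(
        counts=np.moveaxis(pages, 0, 2),
        bin_width=meta["bin_width_ps"],
        rep_period=meta["rep_period_ps"],
        provenance=meta.get("provenance", str(tiff_path)),
    )


def write_map(array: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(array))


def read_map(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_scene(scene: Scene, out_dir, prefix: str = "scene") -> dict[str, Path]:
    """Serialize a scene: label/compartment maps as TIFF, truth as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cell_labels": out_dir / f"{prefix}_cell_labels.tif",
        "compartment_map": out_dir / f"{prefix}_compartments.tif",
        "atp_map": out_dir / f"{prefix}_atp_mM.tif",
        "ground_truth": out_dir / f"{prefix}_ground_truth.csv",
    }
    write_map(scene.cell_labels.astype(np.int32), paths["cell_labels"])
    write_map(scene.compartment_map.astype(np.int32), paths["compartment_map"])
    write_map(scene.atp_map.astype(np.float32), paths["atp_map"])
    scene.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths


def write_fitmap(fitmap: FitMap, out_dir, prefix: str = "fit") -> dict[str, Path]:
    """One 32-bit float TIFF per parameter plus the long CSV table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in ("t1", "t2", "a1_pct", "chi2", "tm"):
        p = out_dir / f"{prefix}_{name}.tif"
        write_map(getattr(fitmap, name).astype(np.float32), p)
        paths[name] = p
    table = out_dir / f"{prefix}_pixels.csv"
    fitmap.to_dataframe().to_csv(table, index=False)
    paths["table"] = table
    return paths
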