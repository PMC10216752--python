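"""End-to-end orchestration: simulate -> fit -> segment -> ROIs -> extract ->
statistics, with a run manifest and make-style stage skipping.

A stage reruns when any of its outputs is missing or older than an input, so
deleting an intermediate forces only that stage and its downstream stages to
rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import (
    extract_parameter_table,
    make_pixel_rois,
    normalize_local_contrast,
    segment_cells,
    zero_nucleus,
)
from .io import read_decay_cube, write_decay_cube, write_fitmap, write_map, write_scene
from .stats import aggregate_by, compare_conditions, kde_normalized
from .synthetic import (
    NUCLEUS,
    AcquisitionConfig,
    CellSpec,
    Scene,
    SceneConfig,
    SensorModel,
    build_scene,
    render_decay_cube,
)
from .tcspc import FitOptions, filter_fits, fit_cube

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_scenes", "demo_config"]


@dataclass
class GroupSpec:
    n_cells: int = 20
    soma_atp: float = 4.0
    axon_atp: float = 2.0


@dataclass
class PipelineConfig:
    """Every stage parameter plus seeds; round-trips through YAML losslessly."""

    seed: int = 0
    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: {
            "control": GroupSpec(),
            "mutant": GroupSpec(soma_atp=3.0),
        }
    )
    reference_group: str = "control"
    soma_radius: int = 4
    nucleus_radius: int = 1
    axon_length: int = 0
    axon_width: int = 2
    atp_noise_sd: float = 0.2
    sensor: SensorModel = field(default_factory=SensorModel)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    chi2_lo: float = 0.7
    chi2_hi: float = 2.0
    contrast_window: int = 15
    min_object_size: int = 5
    stats_level: str = "cell"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = {k: GroupSpec(**v) for k, v in d["groups"].items()}
        for key, typ in (
            ("sensor", SensorModel),
            ("acquisition", AcquisitionConfig),
            ("fit", FitOptions),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "fit" and "lifetime_bounds" in sub:
                    sub["lifetime_bounds"] = tuple(sub["lifetime_bounds"])
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_config() -> PipelineConfig:
    """Small wt-vs-mutant demo that runs in seconds."""
    cfg = PipelineConfig()
    cfg.groups = {
        "control": GroupSpec(n_cells=4),
        "mutant": GroupSpec(n_cells=4, soma_atp=3.0),
    }
    cfg.acquisition = AcquisitionConfig(photons_per_pixel=2000.0, seed=cfg.seed)
    cfg.soma_radius = 3
    return cfg


def _grid_scene_config(group: GroupSpec, cfg: PipelineConfig, seed: int) -> SceneConfig:
    """Lay cells out on a grid with enough margin that they never touch."""
    r = cfg.soma_radius
    pitch = 2 * r + 4 + cfg.axon_length
    cols = max(int(math.ceil(math.sqrt(group.n_cells))), 1)
    rows_n = int(math.ceil(group.n_cells / cols))
    cells = []
    for i in range(group.n_cells):
        cx = (i % cols) * pitch + r + 2
        cy = (i // cols) * pitch + r + 2
        axon = None
        if cfg.axon_length > 0:
            axon = [(cx + r + cfg.axon_length, cy)]
        cells.append(
            CellSpec(
                soma_center=(cx, cy), soma_radius=r, nucleus_radius=cfg.nucleus_radius,
                axon=axon, axon_width=cfg.axon_width,
                soma_atp=group.soma_atp, axon_atp=group.axon_atp,
                atp_noise_sd=cfg.atp_noise_sd,
            )
        )
    width = cols * pitch + 2
    height = rows_n * pitch + 2
    return SceneConfig(width=width, height=height, cells=cells, seed=seed)


def simulate_scenes(cfg: PipelineConfig) -> dict[str, Scene]:
    """Build one scene per group; group seeds derive from the master seed."""
    scenes = {}
    for i, (name, group) in enumerate(sorted(cfg.groups.items())):
        scenes[name] = build_scene(_grid_scene_config(group, cfg, cfg.seed + i), cfg.sensor)
    return scenes


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _needs_run(inputs: list[Path], outputs: list[Path]) -> bool:
    if any(not p.exists() for p in outputs):
        return True
    if not inputs:
        return False
    newest_in = max(p.stat().st_mtime for p in inputs if p.exists())
    oldest_out = min(p.stat().st_mtime for p in outputs)
    return newest_in > oldest_out


def run_pipeline(cfg: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Run all stages in order, skipping stages whose outputs are up to date.

    Returns the run manifest (also written to ``manifest.json``): versions,
    seeds, input hashes, and per-stage row/pixel counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "flimflux_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
        "started": time.time(),
    }
    groups = sorted(cfg.groups)

    # write the config only when it changed, so an unchanged rerun can skip
    config_path = out / "config.yaml"
    config_text = yaml.safe_dump(cfg.to_dict(), sort_keys=False)
    if not config_path.exists() or config_path.read_text() != config_text:
        config_path.write_text(config_text)

    # --- stage: simulate -------------------------------------------------
    cube_paths = {g: out / f"{g}_cube.tif" for g in groups}
    scene_truth = {g: out / f"{g}_ground_truth.csv" for g in groups}
    sim_outputs = (
        list(cube_paths.values())
        + [p.with_suffix(".json") for p in cube_paths.values()]
        + list(scene_truth.values())
        + [out / f"{g}_compartments.tif" for g in groups]
        + [out / f"{g}_cell_labels.tif" for g in groups]
    )
    if force or _needs_run([config_path], sim_outputs):
        scenes = simulate_scenes(cfg)
        n_px = 0
        for i, g in enumerate(groups):
            write_scene(scenes[g], out, prefix=g)
            acq = dataclasses.replace(cfg.acquisition, seed=cfg.seed + 1000 + i)
            cube = render_decay_cube(scenes[g], acq, cfg.sensor)
            write_decay_cube(cube, cube_paths[g], seed=acq.seed)
            n_px += len(scenes[g].ground_truth)
        manifest["stages"]["simulate"] = {"ran": True, "cell_pixels": n_px}
    else:
        manifest["stages"]["simulate"] = {"ran": False}
    log.info("simulate: %s", manifest["stages"]["simulate"])

    # --- stage: fit ------------------------------------------------------
    fit_tables = {g: out / f"{g}_fit_pixels.csv" for g in groups}
    fit_outputs = list(fit_tables.values()) + [out / f"{g}_fit_tm.tif" for g in groups]
    if force or _needs_run(list(cube_paths.values()), fit_outputs):
        n_fit = n_acc = 0
        for g in groups:
            cube = read_decay_cube(cube_paths[g])
            fmap = fit_cube(cube, cfg.fit)
            fmap = filter_fits(fmap, cfg.chi2_lo, cfg.chi2_hi, cfg.fit.min_photons)
            write_fitmap(fmap, out, prefix=f"{g}_fit")
            n_fit += int(np.isfinite(fmap.tm).sum())
            n_acc += int(fmap.accepted.sum())
        manifest["stages"]["fit"] = {"ran": True, "fitted": n_fit, "accepted": n_acc}
    else:
        manifest["stages"]["fit"] = {"ran": False}
    log.info("fit: %s", manifest["stages"]["fit"])

    # --- stage: segment --------------------------------------------------
    seg_paths = {g: out / f"{g}_segmentation.tif" for g in groups}
    seg_inputs = list(cube_paths.values()) + [out / f"{g}_compartments.tif" for g in groups]
    if force or _needs_run(seg_inputs, list(seg_paths.values())):
        import tifffile

        for g in groups:
            cube = read_decay_cube(cube_paths[g])
            photon_img = cube.counts.sum(axis=2).astype(float)
            comp = tifffile.imread(out / f"{g}_compartments.tif")
            win = min(cfg.contrast_window, min(photon_img.shape) - (1 - min(photon_img.shape) % 2))
            if win % 2 == 0:
                win -= 1
            norm = normalize_local_contrast(photon_img, window=max(win, 3))
            norm = zero_nucleus(norm, comp == NUCLEUS)
            labels = segment_cells(norm, min_size=cfg.min_object_size)
            write_map(labels.astype(np.int32), seg_paths[g])
        manifest["stages"]["segment"] = {"ran": True}
    else:
        manifest["stages"]["segment"] = {"ran": False}
    log.info("segment: %s", manifest["stages"]["segment"])

    # --- stage: extract --------------------------------------------------
    params_path = out / "params.csv"
    extract_inputs = list(seg_paths.values()) + list(fit_tables.values())
    if force or _needs_run(extract_inputs, [params_path]):
        import tifffile

        from .tcspc import FitMap

        tables = []
        for g in groups:
            seg = tifffile.imread(seg_paths[g])
            comp = tifffile.imread(out / f"{g}_compartments.tif")
            px = pd.read_csv(fit_tables[g])
            h, w = seg.shape
            fmap = FitMap(shape=(h, w))
            for col, attr in (
                ("t1_ps", "t1"), ("t2_ps", "t2"), ("a1_pct_frac", "a1_pct"),
                ("a2_pct_frac", "a2_pct"), ("chi2", "chi2"), ("tm_ps", "tm"),
                ("n_photons_count", "n_photons"),
            ):
                getattr(fmap, attr)[px["y"], px["x"]] = px[col]
            fmap.accepted[px["y"], px["x"]] = px["accepted"]
            rois = make_pixel_rois(seg, comp, fmap)
            if len(rois) == 0:
                continue
            tbl = extract_parameter_table(fmap, rois)
            tbl.insert(0, "group", g)
            # segmentation labels are per-image; qualify with the group name
            tbl["cell_id"] = [f"{g}_{c}" for c in tbl["cell_id"]]
            tables.append(tbl)
        params = pd.concat(tables, ignore_index=True)
        params.to_csv(params_path, index=False)
        manifest["stages"]["extract"] = {"ran": True, "rows": len(params)}
    else:
        manifest["stages"]["extract"] = {"ran": False}
    log.info("extract: %s", manifest["stages"]["extract"])

    # --- stage: stats ----------------------------------------------------
    summary_path = out / "summary.csv"
    effects_path = out / "effects.csv"
    kde_path = out / "kde.csv"
    if force or _needs_run([params_path], [summary_path, effects_path, kde_path]):
        params = pd.read_csv(params_path)
        summary = aggregate_by(params, ["group", "compartment"], level=cfg.stats_level)
        summary.to_csv(summary_path, index=False)
        cell_tm = (
            params[params["compartment"] == "soma"]
            .groupby(["group", "cell_id"], observed=True)["tm_ps"].mean().reset_index()
        )
        effects = compare_conditions(cell_tm, cfg.reference_group, value="tm_ps")
        effects.to_csv(effects_path, index=False)
        kde_rows = []
        for g, sub in params.groupby("group", observed=True):
            x, dens = kde_normalized(sub["tm_ps"].dropna().to_numpy())
            kde_rows.append(pd.DataFrame({"group": g, "tm_ps": x, "density_per_ps": dens}))
        pd.concat(kde_rows, ignore_index=True).to_csv(kde_path, index=False)
        manifest["stages"]["stats"] = {"ran": True, "groups": len(effects)}
    else:
        manifest["stages"]["stats"] = {"ran": False}
    log.info("stats: %s", manifest["stages"]["stats"])

    manifest["input_hashes"] = {str(p.name): _file_hash(p) for p in cube_paths.values()}
    manifest["finished"] = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
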