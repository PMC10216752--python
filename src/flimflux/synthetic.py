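"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Generates neuron scenes (soma/axon/nucleus geometry with per-pixel ATP),
pulsed-excitation TCSPC decay cubes with Poisson photon noise, HPLC-style
chromatograms and extracellular-flux plate traces. Every generator takes an
explicit seed; no global RNG state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, line
from skimage.morphology import disk as disk_footprint

from .tcspc import DecayCube, apply_shift, convolve_irf, incomplete_decay

__all__ = [
    "SensorModel",
    "AcquisitionConfig",
    "CellSpec",
    "SceneConfig",
    "Scene",
    "Chromatogram",
    "WellSpec",
    "FluxDesign",
    "FluxPlate",
    "FLUX_BLOCKS",
    "BACKGROUND",
    "SOMA",
    "AXON",
    "NUCLEUS",
    "COMPARTMENT_NAMES",
    "atp_to_bound_fraction",
    "build_scene",
    "render_decay_cube",
    "generate_chromatogram",
    "generate_flux_traces",
]

# compartment codes in Scene.compartment_map
BACKGROUND, SOMA, AXON, NUCLEUS = 0, 1, 2, 3
COMPARTMENT_NAMES = {BACKGROUND: "background", SOMA: "soma", AXON: "axon", NUCLEUS: "nucleus"}


@dataclass
class SensorModel:
    """ATP biosensor: donor lifetime shortens with the ATP-bound fraction.

    The dose-response is a Hill curve; a non-binding variant (``binding_competent
    = False``) never leaves the free state and serves as the no-FRET lifetime
    reference.
    """

    kd: float = 3.3  # mM
    hill_n: float = 2.0
    tau_free: float = 1750.0  # ps
    tau_fret: float = 700.0  # ps
    binding_competent: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.tau_fret < self.tau_free):
            raise ValueError("require 0 < tau_fret < tau_free")
        if self.kd <= 0 or self.hill_n <= 0:
            raise ValueError("kd and hill_n must be positive")


@dataclass
class AcquisitionConfig:
    n_bins: int = 256
    bin_width: float = 48.8  # ps
    rep_period: float = 12_500.0  # ps (80 MHz class)
    photons_per_pixel: float = 5000.0
    irf_shift: float = 0.0  # channels
    irf_sigma: float = 0.0  # ps; 0 = ideal pulse
    background_rate: float = 0.0  # counts/bin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins * self.bin_width > self.rep_period + 1e-9:
            raise ValueError("n_bins * bin_width must not exceed rep_period")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")


def atp_to_bound_fraction(atp, sensor: SensorModel):
    """Hill-curve bound fraction atp^n / (kd^n + atp^n); 0 for non-binders."""
    atp = np.asarray(atp, dtype=float)
    if np.any(atp < 0):
        raise ValueError("atp must be non-negative")
    if not sensor.binding_competent:
        return np.zeros_like(atp) if atp.ndim else 0.0
    with np.errstate(divide="ignore"):
        frac = atp**sensor.hill_n / (sensor.kd**sensor.hill_n + atp**sensor.hill_n)
    return frac if atp.ndim else float(frac)


@dataclass
class CellSpec:
    """Geometry and ATP levels for one simulated neuron."""

    soma_center: tuple[int, int]  # (x, y)
    soma_radius: int
    nucleus_radius: int = 0
    axon: list[tuple[int, int]] | None = None  # waypoints (x, y), starts at soma edge
    axon_width: int = 2
    soma_atp: float = 4.0  # mM
    axon_atp: float = 2.0  # mM
    atp_noise_sd: float = 0.0  # mM, per-pixel spatial noise


@dataclass
class SceneConfig:
    width: int = 32
    height: int = 32
    cells: list[CellSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class Scene:
    width: int
    height: int
    cell_labels: np.ndarray  # int map, 0 = background
    compartment_map: np.ndarray  # codes above
    atp_map: np.ndarray  # mM per pixel
    ground_truth: pd.DataFrame  # per cell pixel
    sensor: SensorModel


def _axon_mask(spec: CellSpec, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    pts = [spec.soma_center] + list(spec.axon or [])
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(int(y0), int(x0), int(y1), int(x1))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    half = max(spec.axon_width // 2, 0)
    if half:
        mask = ndimage.binary_dilation(mask, structure=disk_footprint(half))
    return mask


def build_scene(config: SceneConfig, sensor: SensorModel | None = None) -> Scene:
    """Rasterize cells into label/compartment/ATP maps with per-pixel truth.

    Soma pixels take precedence over axon pixels; nucleus pixels (inside the
    soma) carry no ATP ground truth and are excluded from the truth table.
    Overlapping cells are rejected. Deterministic given ``config.seed``.
    """
    sensor = sensor or SensorModel()
    rng = np.random.default_rng(config.seed)
    shape = (config.height, config.width)
    labels = np.zeros(shape, dtype=int)
    comp = np.zeros(shape, dtype=int)
    atp = np.zeros(shape, dtype=float)

    for idx, spec in enumerate(config.cells, start=1):
        cx, cy = spec.soma_center
        rr, cc = disk((cy, cx), spec.soma_radius, shape=shape)
        soma = np.zeros(shape, dtype=bool)
        soma[rr, cc] = True
        axon = _axon_mask(spec, shape) & ~soma if spec.axon else np.zeros(shape, dtype=bool)
        cell = soma | axon
        clash = (labels > 0) & cell
        if clash.any():
            other = int(labels[clash][0])
            raise ValueError(f"cell {idx} overlaps cell {other} at {int(clash.sum())} pixel(s)")
        if not soma.any():
            raise ValueError(f"cell {idx} has no soma pixels inside the frame")
        labels[cell] = idx
        comp[soma] = SOMA
        comp[axon] = AXON
        if spec.nucleus_radius > 0:
            rr, cc = disk((cy, cx), spec.nucleus_radius, shape=shape)
            nuc = np.zeros(shape, dtype=bool)
            nuc[rr, cc] = True
            nuc &= soma  # nucleus is a subset of the cell
            comp[nuc] = NUCLEUS
        for mask, level in ((comp == SOMA) & cell, spec.soma_atp), ((comp == AXON) & cell, spec.axon_atp):
            vals = np.full(int(mask.sum()), float(level))
            if spec.atp_noise_sd > 0:
                vals = vals + rng.normal(0.0, spec.atp_noise_sd, vals.size)
            atp[mask] = np.clip(vals, 0.0, None)

    cytosol = (comp == SOMA) | (comp == AXON)
    ys, xs = np.nonzero(cytosol)
    bound = atp_to_bound_fraction(atp[ys, xs], sensor)
    truth = pd.DataFrame(
        {
            "x": xs,
            "y": ys,
            "cell_id": labels[ys, xs],
            "compartment": [COMPARTMENT_NAMES[c] for c in comp[ys, xs]],
            "atp_mM": atp[ys, xs],
            "bound_fraction": bound,
            "tau_free_ps": sensor.tau_free,
            "tau_fret_ps": sensor.tau_fret,
            "expected_tm_ps": bound * sensor.tau_fret + (1.0 - bound) * sensor.tau_free,
        }
    )
    return Scene(config.width, config.height, labels, comp, atp, truth, sensor)


def render_decay_cube(
    scene: Scene, acq: AcquisitionConfig, sensor: SensorModel | None = None
) -> DecayCube:
    """Render a TCSPC decay cube from a scene.

    Per cytosolic pixel the expected curve is the bound-fraction mixture of
    incomplete decays at tau_fret and tau_free, optionally IRF-convolved and
    shifted, normalized to ``photons_per_pixel`` expected counts, plus a flat
    background. Counts are Poisson with ``acq.seed``; background and nucleus
    pixels contain only background counts.
    """
    sensor = sensor or scene.sensor
    rng = np.random.default_rng(acq.seed)
    t_axis = (np.arange(acq.n_bins) + 0.5) * acq.bin_width

    def shape_curve(tau: float) -> np.ndarray:
        c = incomplete_decay(t_axis, tau, acq.rep_period)
        if acq.irf_sigma > 0:
            c = convolve_irf(c, acq.irf_sigma, acq.bin_width)
        if acq.irf_shift != 0:
            c = apply_shift(c, acq.irf_shift)
        return c

    curve_fret = shape_curve(sensor.tau_fret)
    curve_free = shape_curve(sensor.tau_free)

    h, w = scene.compartment_map.shape
    expected = np.full((h, w, acq.n_bins), float(acq.background_rate))
    truth = scene.ground_truth
    f = truth["bound_fraction"].to_numpy()[:, None]
    mix = f * curve_fret[None, :] + (1.0 - f) * curve_free[None, :]
    mix *= acq.photons_per_pixel / mix.sum(axis=1, keepdims=True)
    expected[truth["y"].to_numpy(), truth["x"].to_numpy()] += mix

    counts = rng.poisson(expected).astype(np.uint16)
    return DecayCube(
        counts=counts,
        bin_width=acq.bin_width,
        rep_period=acq.rep_period,
        provenance=f"synthetic seed={acq.seed}",
    )


# ---------------------------------------------------------------------------
# chromatograms


@dataclass
class Chromatogram:
    trace: pd.DataFrame  # columns: time_min, signal
    true_areas: dict[str, float]
    retention_times: dict[str, float]
    peak_sigma: dict[str, float]
    overlap_warning: bool = False


DEFAULT_RETENTION = {"AMP": 2.0, "ADP": 3.5, "ATP": 5.0}  # min, elution order


def generate_chromatogram(
    amounts: dict[str, float],
    calib: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    retention_times: dict[str, float] | None = None,
    peak_sigma: float | dict[str, float] = 0.08,
    baseline: float = 0.0,
    t_max: float | None = None,
    dt: float = 0.002,
) -> Chromatogram:
    """Sum-of-Gaussians trace; peak area = amount x calibration factor.

    Peaks closer than 3 sigma raise an overlap warning flag. Gaussian noise
    with ``noise_sd`` is added reproducibly from ``seed``.
    """
    rts = dict(retention_times or DEFAULT_RETENTION)
    missing = set(amounts) - set(rts)
    if missing:
        raise ValueError(f"no retention time for analytes: {sorted(missing)}")
    sig = {a: (peak_sigma[a] if isinstance(peak_sigma, dict) else float(peak_sigma)) for a in amounts}

    overlap = False
    names = sorted(amounts, key=lambda a: rts[a])
    for a, b in zip(names[:-1], names[1:]):
        if rts[b] - rts[a] < 3.0 * max(sig[a], sig[b]):
            overlap = True
            warnings.warn(f"peaks {a} and {b} closer than 3 sigma", stacklevel=2)

    t_end = t_max if t_max is not None else max(rts[a] for a in amounts) + 2.0
    t = np.arange(0.0, t_end, dt)
    signal = np.full_like(t, float(baseline))
    areas: dict[str, float] = {}
    for a in amounts:
        area = amounts[a] * calib[a]
        areas[a] = area
        amp = area / (sig[a] * np.sqrt(2.0 * np.pi))
        signal = signal + amp * np.exp(-0.5 * ((t - rts[a]) / sig[a]) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, t.size)
    trace = pd.DataFrame({"time_min": t, "signal": signal})
    return Chromatogram(trace, areas, {a: rts[a] for a in amounts}, sig, overlap)


# ---------------------------------------------------------------------------
# extracellular flux plates

FLUX_BLOCKS = ("baseline", "glucose", "oligomycin", "fccp", "rotenone_antimycin")


@dataclass
class WellSpec:
    well: str
    ocr_by_block: dict[str, float]  # true OCR level per block
    ecar_by_block: dict[str, float]
    group: str = "control"
    replicate: int = 1  # biological replicate id
    excluded: bool = False


@dataclass
class FluxDesign:
    wells: list[WellSpec]
    cycles_per_block: int = 3  # each block measured in triplicate
    points_per_measurement: int = 7
    measurement_minutes: float = 3.0
    noise_sd_ocr: float = 0.0  # noise on the raw O2 trace
    noise_sd_ecar: float = 0.0


@dataclass
class FluxPlate:
    traces: pd.DataFrame
    # columns: well, group, replicate, block, cycle, time_min, o2_signal, ph_signal
    true_levels: pd.DataFrame  # well, group, replicate, block, ocr_true, ecar_true
    excluded_wells: list[str]
    design: FluxDesign


def generate_flux_traces(design: FluxDesign, seed: int = 0) -> FluxPlate:
    """Piecewise-constant rates rendered as raw traces plus noise.

    The O2 signal falls at slope -OCR within each measurement cycle and the
    acidification signal rises at slope +ECAR, so robust regression on the raw
    traces recovers the block levels (consumption positive).
    """
    if design.points_per_measurement < 2:
        raise ValueError("need at least 2 timepoints per measurement to define a slope")
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    t_local = np.linspace(0.0, design.measurement_minutes, design.points_per_measurement)
    for wspec in design.wells:
        missing = [b for b in FLUX_BLOCKS if b not in wspec.ocr_by_block or b not in wspec.ecar_by_block]
        if missing:
            raise ValueError(f"well {wspec.well} missing blocks: {missing}")
        t0 = 0.0
        o2_level, ph_level = 200.0, 10.0  # arbitrary raw-signal origins
        for block in FLUX_BLOCKS:
            ocr = float(wspec.ocr_by_block[block])
            ecar = float(wspec.ecar_by_block[block])
            truth_rows.append(
                {"well": wspec.well, "group": wspec.group, "replicate": wspec.replicate,
                 "block": block, "ocr_true": ocr, "ecar_true": ecar}
            )
            for cycle in range(design.cycles_per_block):
                o2 = o2_level - ocr * t_local
                ph = ph_level + ecar * t_local
                if design.noise_sd_ocr > 0:
                    o2 = o2 + rng.normal(0.0, design.noise_sd_ocr, o2.size)
                if design.noise_sd_ecar > 0:
                    ph = ph + rng.normal(0.0, design.noise_sd_ecar, ph.size)
                for k in range(t_local.size):
                    rows.append(
                        {"well": wspec.well, "group": wspec.group,
                         "replicate": wspec.replicate, "block": block, "cycle": cycle,
                         "time_min": t0 + t_local[k], "o2_signal": o2[k],
                         "ph_signal": ph[k]}
                    )
                t0 += design.measurement_minutes + 1.0  # mixing/settling gap
    traces = pd.DataFrame(rows)
    true_levels = pd.DataFrame(truth_rows)
    excluded = [w.well for w in design.wells if w.excluded]
    return FluxPlate(traces, true_levels, excluded, design)
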