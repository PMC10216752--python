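"""Bulk metabolic-assay calculators.

HPLC peak integration with external-standard calibration, ATP/ADP ratio and
adenylate energy charge; Theil-Sen robust rates for extracellular-flux traces
with per-block pooling and derived respiration metrics (proton leak, maximal
respiratory capacity, glycolytic increase); MTT plate normalization to
mock-treated wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import FLUX_BLOCKS, FluxPlate

__all__ = [
    "NucleotidePanel",
    "RespirationMetrics",
    "integrate_peaks",
    "calibrate",
    "adenylate_energy_charge",
    "atp_adp_ratio",
    "nucleotide_panel",
    "rate_robust",
    "well_rates",
    "block_levels",
    "respiration_metrics",
    "respiration_metrics_table",
    "mtt_normalize",
]


@dataclass
class NucleotidePanel:
    atp: float
    adp: float
    amp: float
    atp_adp_ratio: float
    aec: float


@dataclass
class RespirationMetrics:
    basal_ocr: float
    atp_linked_ocr: float
    proton_leak_ocr: float
    max_capacity_ocr: float
    non_mito_ocr: float
    glycolytic_increase_ecar: float
    non_glycolytic_ecar: float
    leak_flagged: bool = False  # proton_leak < 0


# ---------------------------------------------------------------------------
# HPLC


def integrate_peaks(
    chromatogram: pd.DataFrame,
    retention_windows: dict[str, tuple[float, float]],
    time_col: str = "time_min",
    signal_col: str = "signal",
) -> dict[str, float]:
    """Baseline-subtracted trapezoidal peak area per retention window.

    The baseline is the straight line between the trace values at the window
    endpoints. Windows must be disjoint and inside the trace.
    """
    t = chromatogram[time_col].to_numpy(dtype=float)
    y = chromatogram[signal_col].to_numpy(dtype=float)
    spans = sorted(retention_windows.items(), key=lambda kv: kv[1][0])
    for (na, (a0, a1)), (nb, (b0, _)) in zip(spans[:-1], spans[1:]):
        if a1 > b0:
            raise ValueError(f"retention windows {na} and {nb} overlap")
    areas: dict[str, float] = {}
    for name, (w0, w1) in retention_windows.items():
        if w0 < t[0] or w1 > t[-1] or w0 >= w1:
            raise ValueError(f"window {name} = ({w0}, {w1}) outside trace [{t[0]}, {t[-1]}]")
        sel = (t >= w0) & (t <= w1)
        ts, ys = t[sel], y[sel]
        baseline = np.interp(ts, [ts[0], ts[-1]], [ys[0], ys[-1]])
        areas[name] = float(np.trapezoid(ys - baseline, ts))
    return areas


def calibrate(
    areas: dict[str, float],
    standard_areas: dict[str, np.ndarray],
    standard_amounts: dict[str, np.ndarray],
) -> dict[str, float]:
    """Concentrations from external standards via a through-origin linear
    response factor per analyte (least squares over all standard points)."""
    out: dict[str, float] = {}
    for name, area in areas.items():
        sa = np.atleast_1d(np.asarray(standard_areas[name], dtype=float))
        sc = np.atleast_1d(np.asarray(standard_amounts[name], dtype=float))
        if np.any(sa <= 0):
            raise ValueError(f"non-positive standard area for {name}")
        factor = float(np.sum(sa * sc) / np.sum(sc**2))  # area per unit amount
        out[name] = float(area / factor)
    return out


def adenylate_energy_charge(atp: float, adp: float, amp: float) -> float:
    """AEC = (ATP + 0.5 ADP) / (AMP + ADP + ATP)."""
    if atp < 0 or adp < 0 or amp < 0:
        raise ValueError("concentrations must be non-negative")
    total = atp + adp + amp
    if total <= 0:
        raise ValueError("AEC undefined for an all-zero panel")
    return (atp + 0.5 * adp) / total


def atp_adp_ratio(atp: float, adp: float) -> float:
    """ATP/ADP; undefined (NaN, flagged) when ADP is zero."""
    if adp == 0:
        warnings.warn("ADP is zero: ATP/ADP ratio undefined", stacklevel=2)
        return float("nan")
    return atp / adp


def nucleotide_panel(atp: float, adp: float, amp: float) -> NucleotidePanel:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = atp_adp_ratio(atp, adp) if adp > 0 else float("nan")
    return NucleotidePanel(atp, adp, amp, ratio, adenylate_energy_charge(atp, adp, amp))


# ---------------------------------------------------------------------------
# extracellular flux


def rate_robust(times, values, method: str = "theil-sen") -> float:
    """Robust slope of a raw trace: Theil-Sen (median of pairwise slopes) by
    default, Huber M-estimate as an option."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("duplicate timestamps: slope undefined")
    if method == "theil-sen":
        return float(sps.theilslopes(y, t).slope)
    if method == "huber":
        import statsmodels.api as sm

        exog = sm.add_constant(t)
        fit = sm.RLM(y, exog, M=sm.robust.norms.HuberT()).fit()
        return float(fit.params[1])
    raise ValueError(f"unknown method {method!r}")


def well_rates(plate: FluxPlate, method: str = "theil-sen") -> pd.DataFrame:
    """Per-well per-cycle OCR/ECAR from the raw traces.

    OCR = -slope(O2 signal) so consumption is positive; ECAR = +slope of the
    acidification signal.
    """
    rows = []
    for (well, group, rep, block, cycle), sub in plate.traces.groupby(
        ["well", "group", "replicate", "block", "cycle"], observed=True, sort=False
    ):
        rows.append(
            {"well": well, "group": group, "replicate": rep, "block": block,
             "cycle": cycle,
             "ocr": -rate_robust(sub["time_min"], sub["o2_signal"], method),
             "ecar": rate_robust(sub["time_min"], sub["ph_signal"], method)}
        )
    return pd.DataFrame(rows)


def block_levels(
    plate: FluxPlate,
    method: str = "theil-sen",
    exclude_wells: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well per-block mean cycle rate, then equal-weight pooling of
    technical-replicate wells to one value per biological replicate.

    Wells flagged in the plate design or listed in ``exclude_wells`` are
    dropped before pooling. Returns (per_well, per_replicate) frames.
    """
    excluded = set(plate.excluded_wells) | set(exclude_wells or ())
    rates = well_rates(plate, method)
    rates = rates[~rates["well"].isin(excluded)]
    if rates.empty:
        warnings.warn("all wells excluded: empty block levels", stacklevel=2)
        empty = pd.DataFrame(columns=["well", "group", "replicate", "block", "ocr", "ecar"])
        return empty, empty.drop(columns=["well"])
    per_well = (
        rates.groupby(["well", "group", "replicate", "block"], observed=True, sort=False)[["ocr", "ecar"]]
        .mean()
        .reset_index()
    )
    per_replicate = (
        per_well.groupby(["group", "replicate", "block"], observed=True, sort=False)[["ocr", "ecar"]]
        .mean()
        .reset_index()
    )
    return per_well, per_replicate


def respiration_metrics(ocr_by_block: dict[str, float], ecar_by_block: dict[str, float]) -> RespirationMetrics:
    """Derived respiration metrics from one set of block levels.

    non_mito = post-rotenone/antimycin OCR; basal = baseline OCR - non_mito;
    atp_linked = baseline OCR - post-oligomycin OCR; proton_leak =
    post-oligomycin OCR - non_mito; max_capacity = post-FCCP OCR - non_mito;
    glycolytic_increase = post-glucose ECAR - baseline ECAR; non_glycolytic =
    post-2-DG ECAR. By construction basal = atp_linked + proton_leak.

    Baseline OCR here means the pre-oligomycin level (the glucose/pyruvate
    block, the last block before complex-V inhibition).
    """
    missing = [b for b in FLUX_BLOCKS if b not in ocr_by_block or b not in ecar_by_block]
    if missing:
        raise ValueError(f"missing blocks: {missing}")
    pre_oligo = float(ocr_by_block["glucose"])
    post_oligo = float(ocr_by_block["oligomycin"])
    non_mito = float(ocr_by_block["rotenone_antimycin"])
    leak = post_oligo - non_mito
    if leak < 0:
        warnings.warn("negative proton leak flagged", stacklevel=2)
    return RespirationMetrics(
        basal_ocr=pre_oligo - non_mito,
        atp_linked_ocr=pre_oligo - post_oligo,
        proton_leak_ocr=leak,
        max_capacity_ocr=float(ocr_by_block["fccp"]) - non_mito,
        non_mito_ocr=non_mito,
        glycolytic_increase_ecar=float(ecar_by_block["glucose"]) - float(ecar_by_block["baseline"]),
        non_glycolytic_ecar=float(ecar_by_block["rotenone_antimycin"]),
        leak_flagged=leak < 0,
    )


def respiration_metrics_table(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Respiration metrics per (group, biological replicate) from pooled block levels."""
    rows = []
    for (group, rep), sub in per_replicate.groupby(["group", "replicate"], observed=True, sort=False):
        ocr = dict(zip(sub["block"], sub["ocr"]))
        ecar = dict(zip(sub["block"], sub["ecar"]))
        m = respiration_metrics(ocr, ecar)
        rows.append({"group": group, "replicate": rep, **m.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MTT


def mtt_normalize(
    plate: pd.DataFrame,
    mock_label: str = "mock",
    line_col: str = "line",
    treatment_col: str = "treatment",
    value_col: str = "absorbance",
) -> pd.DataFrame:
    """Normalize absorbance to the mean of mock-treated wells within each line."""
    out = plate.copy()
    out["viability_norm"] = np.nan
    for ln, sub in plate.groupby(line_col, observed=True):
        mock = sub.loc[sub[treatment_col] == mock_label, value_col]
        if len(mock) == 0:
            raise ValueError(f"line {ln!r} has no mock-treated wells")
        mock_mean = mock.mean()
        if mock_mean == 0:
            raise ValueError(f"line {ln!r} mock mean is zero")
        out.loc[sub.index, "viability_norm"] = sub[value_col] / mock_mean
    return out
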