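"""Photon-image processing chain: local-contrast normalization, nucleus
zeroing, cell segmentation, single-pixel compartment ROIs, and the
mitochondrial-mask mean-intensity metric.

Coordinates are 0-based with (x, y) = (column, row), origin top-left.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .synthetic import AXON, NUCLEUS, SOMA
from .tcspc import FitMap

__all__ = [
    "normalize_local_contrast",
    "zero_nucleus",
    "segment_cells",
    "make_pixel_rois",
    "extract_parameter_table",
    "mito_mask_mean",
]

log = logging.getLogger(__name__)


def normalize_local_contrast(image: np.ndarray, window: int = 31, eps: float = 1e-6) -> np.ndarray:
    """(I - mu_w)/max(sigma_w, eps) with box-filter local statistics, rescaled
    to [0, 1].

    The box filter is the integral-image local mean; the result is invariant
    (up to the eps floor) to global affine intensity changes aI + b, a > 0.
    A contrast-free (constant) image maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(image.shape):
        raise ValueError(f"window {window} larger than image {image.shape}")
    mu = ndimage.uniform_filter(image, size=window, mode="reflect")
    mu2 = ndimage.uniform_filter(image**2, size=window, mode="reflect")
    sigma = np.sqrt(np.maximum(mu2 - mu**2, 0.0))
    out = (image - mu) / np.maximum(sigma, eps)
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def zero_nucleus(image: np.ndarray, nucleus_mask: np.ndarray) -> np.ndarray:
    """Set masked pixels to 0, leave the rest untouched."""
    image = np.asarray(image)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if nucleus_mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    out = image.copy()
    out[nucleus_mask] = 0
    return out


def segment_cells(
    image: np.ndarray,
    threshold_method: str = "otsu",
    min_size: int = 20,
    connectivity: int = 2,
    threshold: float | None = None,
    fill_holes: bool = True,
) -> np.ndarray:
    """Global threshold -> hole filling -> connected components -> small-object
    removal.

    Default Otsu threshold and 8-connectivity; background gets label 0. An
    empty foreground yields an all-zero label map with a warning. Hole filling
    closes interior dropouts where the contrast-normalized image is pure noise
    (windows fully inside a flat cell); disable with ``fill_holes=False``.
    """
    image = np.asarray(image, dtype=float)
    if threshold is not None:
        thr = float(threshold)
    elif threshold_method == "otsu":
        if np.ptp(image) < 1e-12:
            warnings.warn("constant image: empty segmentation", stacklevel=2)
            return np.zeros(image.shape, dtype=int)
        thr = threshold_otsu(image)
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    fg = image > thr
    if not fg.any():
        warnings.warn("empty foreground after thresholding", stacklevel=2)
        return np.zeros(image.shape, dtype=int)
    if fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    labels = cc_label(fg, connectivity=connectivity)
    if min_size > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_size)
        fg &= ~np.isin(labels, small[small > 0])
        labels = cc_label(fg, connectivity=connectivity)
    return labels


def make_pixel_rois(
    label_map: np.ndarray,
    compartment_map: np.ndarray,
    fitmap: FitMap | None = None,
) -> pd.DataFrame:
    """Single-pixel ROIs: one row per foreground, non-nucleus pixel whose fit
    (if a FitMap is given) is accepted.

    Columns: cell_id, compartment ('soma'/'axon'), x, y. Foreground pixels
    without a soma/axon compartment assignment are dropped and counted in the
    log. Nucleus pixels never appear.
    """
    label_map = np.asarray(label_map)
    compartment_map = np.asarray(compartment_map)
    if label_map.shape != compartment_map.shape:
        raise ValueError("label and compartment maps must share a shape")
    if fitmap is not None and fitmap.shape != label_map.shape:
        raise ValueError("fitmap shape must match the label map")

    fg = label_map > 0
    keep = fg & ((compartment_map == SOMA) | (compartment_map == AXON))
    n_dropped = int((fg & ~keep & (compartment_map != NUCLEUS)).sum())
    if n_dropped:
        log.info("dropped %d foreground pixels with no compartment", n_dropped)
    if fitmap is not None:
        keep &= fitmap.accepted
    ys, xs = np.nonzero(keep)
    if ys.size == 0:
        warnings.warn("empty ROI set: no accepted foreground pixels", stacklevel=2)
    rois = pd.DataFrame(
        {
            "cell_id": label_map[ys, xs],
            "compartment": np.where(compartment_map[ys, xs] == SOMA, "soma", "axon"),
            "x": xs,
            "y": ys,
        }
    )
    return rois


def extract_parameter_table(fitmap: FitMap, rois: pd.DataFrame) -> pd.DataFrame:
    """Join ROI pixels to per-pixel fit parameters; one row per ROI entry."""
    if len(rois) == 0:
        raise ValueError("ROI set is empty")
    ys = rois["y"].to_numpy()
    xs = rois["x"].to_numpy()
    out = rois.copy().reset_index(drop=True)
    out["t1_ps"] = fitmap.t1[ys, xs]
    out["t2_ps"] = fitmap.t2[ys, xs]
    out["a1_pct_frac"] = fitmap.a1_pct[ys, xs]
    out["a2_pct_frac"] = fitmap.a2_pct[ys, xs]
    out["chi2"] = fitmap.chi2[ys, xs]
    out["tm_ps"] = fitmap.tm[ys, xs]
    out["n_photons_count"] = fitmap.n_photons[ys, xs]
    return out


def mito_mask_mean(intensity_image: np.ndarray, mask_threshold: float) -> tuple[float, int]:
    """Mean intensity within the thresholded (binary) mitochondrial mask.

    Returns (mean, mask_area). An empty mask is flagged with a warning and a
    NaN mean.
    """
    img = np.asarray(intensity_image, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    mask = img > mask_threshold
    area = int(mask.sum())
    if area == 0:
        warnings.warn("empty mitochondrial mask: mean undefined", stacklevel=2)
        return float("nan"), 0
    return float(img[mask].mean()), area
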