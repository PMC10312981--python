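"""Adaptive tumor/stroma segmentation and cell-type labeling.

Region masks come from per-sample Multi-Otsu thresholding of smoothed,
log-transformed tumor-marker and pan-leukocyte channels: four intensity
classes (non-tissue background, tissue background, low- and high-intensity
foreground), thresholded at the mean of the low-intensity-foreground class,
then cleaned by morphological closing and small-hole/object removal. Stroma
is the leukocyte mask minus the tumor mask. Cell labels use an exact
two-cluster 1D k-means on per-cell log intensities with the upper-cluster
mean as threshold; antigen-loaded macrophages are called on the
upper-quartile average of cytoplasmic tumor signal.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.morphology import closing

from .contacts import extract_membrane
from .model import (
    CellTable,
    LabelMask,
    MarkerImage,
    RegionMasks,
    ThresholdModel,
)

__all__ = [
    "preprocess_channel",
    "multi_otsu",
    "region_mask_from_channel",
    "tumor_stroma",
    "segment_regions",
    "assign_region",
    "two_means_split",
    "classify_cells",
    "call_loaded_macrophages",
]


def preprocess_channel(image: MarkerImage, channel: str) -> np.ndarray:
    """Gaussian blur (sigma = 1 px) then log2(x+1); output is >= 0."""
    raw = image[channel]
    smoothed = gaussian(raw, sigma=1.0, preserve_range=True)
    return np.log2(np.maximum(smoothed, 0.0) + 1.0)


def _level_histogram(values: np.ndarray, max_levels: int):
    """Distinct values and counts, binned to ``max_levels`` when too many."""
    levels, counts = np.unique(values, return_counts=True)
    if levels.size > max_levels:
        lo, hi = float(levels[0]), float(levels[-1])
        edges = np.linspace(lo, hi, max_levels + 1)
        counts, _ = np.histogram(values, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        levels, counts = centers[keep], counts[keep]
    return levels.astype(float), counts.astype(float)


def multi_otsu(
    values, n_classes: int = 4, channel: str = "", max_levels: int = 256
) -> ThresholdModel:
    """Exact Multi-Otsu thresholds maximizing between-class variance.

    Works on the histogram of distinct values (equal-width binned to at most
    ``max_levels`` levels first when there are more); the optimal contiguous
    partition into ``n_classes`` is found by dynamic programming over all
    cut positions, which is exhaustive over threshold placements. Reported
    thresholds are midpoints between the bordering levels of consecutive
    classes, so they fall strictly between occupied intensity levels.
    """
    values = np.asarray(values, float).ravel()
    levels, counts = _level_histogram(values, max_levels)
    n = levels.size
    if n < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct values, got {n}"
        )
    w = np.concatenate([[0.0], np.cumsum(counts)])
    s = np.concatenate([[0.0], np.cumsum(counts * levels)])
    # f[i, j] = (sum of class weights*means)^2 / weight for levels[i:j]
    W = w[None, :] - w[:, None]
    S = s[None, :] - s[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(W > 0, S * S / np.where(W > 0, W, 1.0), -np.inf)

    # D[j] = best objective for levels[0:j] split into c classes
    D = f[0, :].copy()
    choice = []
    for c in range(1, n_classes):
        cand = D[:, None] + f  # cand[i, j]: last class is levels[i:j]
        cut = np.nanargmax(np.where(np.isfinite(cand), cand, -np.inf), axis=0)
        newD = cand[cut, np.arange(n + 1)]
        choice.append(cut)
        D = newD
    cuts = []
    j = n
    for c in range(n_classes - 1, 0, -1):
        i = int(choice[c - 1][j])
        cuts.append(i)
        j = i
    cuts = cuts[::-1]
    thresholds = np.array(
        [0.5 * (levels[c - 1] + levels[c]) for c in cuts], dtype=float
    )
    bounds = [0, *cuts, n]
    class_means = np.array(
        [
            (s[bounds[k + 1]] - s[bounds[k]]) / (w[bounds[k + 1]] - w[bounds[k]])
            for k in range(n_classes)
        ]
    )
    return ThresholdModel(channel=channel, thresholds=thresholds, class_means=class_means)


def _remove_small_components(binary: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_size`` pixels."""
    lbl, n = ndimage.label(binary, structure=np.ones((3, 3), bool))
    if n == 0:
        return binary
    sizes = np.bincount(lbl.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lbl]


def _fill_small_holes(binary: np.ndarray, max_size_exclusive: int) -> np.ndarray:
    """Fill background components (4-connected, not touching the border)
    with fewer than ``max_size_exclusive`` pixels."""
    lbl, n = ndimage.label(~binary)
    if n == 0:
        return binary
    border_labels = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    sizes = np.bincount(lbl.ravel())
    fill = sizes < max_size_exclusive
    fill[border_labels] = False
    fill[0] = False
    return binary | fill[lbl]


def region_mask_from_channel(
    smoothed_log: np.ndarray,
    model: Optional[ThresholdModel] = None,
    min_feature_px: int = 2500,
    closing_px: int = 10,
) -> np.ndarray:
    """Binary region mask from a smoothed log-intensity raster.

    Threshold: mean of the low-intensity-foreground class (3rd of 4);
    cleanup: 10x10-square closing, fill holes under ``min_feature_px``
    pixels, drop 8-connected objects under ``min_feature_px`` pixels.
    """
    if model is None:
        model = multi_otsu(smoothed_log, n_classes=4)
    if len(model.class_means) != 4:
        raise ValueError("region thresholding expects a 4-class model")
    threshold = float(model.class_means[2])
    mask = smoothed_log > threshold
    mask = closing(mask, footprint=np.ones((closing_px, closing_px), bool))
    mask = _fill_small_holes(mask, min_feature_px)
    mask = _remove_small_components(mask, min_feature_px)
    if not mask.any():
        warnings.warn("region mask empty after cleanup", stacklevel=2)
    return mask


def tumor_stroma(melanoma_mask: np.ndarray, cd45_mask: np.ndarray) -> RegionMasks:
    """Tumor is the tumor-marker mask; stroma is leukocyte mask minus tumor."""
    melanoma_mask = np.asarray(melanoma_mask, bool)
    cd45_mask = np.asarray(cd45_mask, bool)
    if melanoma_mask.shape != cd45_mask.shape:
        raise ValueError("mask shape mismatch")
    return RegionMasks(tumor=melanoma_mask, stroma=cd45_mask & ~melanoma_mask)


def segment_regions(
    image: MarkerImage, tumor_channel: str, leukocyte_channel: str
) -> RegionMasks:
    """Full adaptive tumor/stroma segmentation from two raw channels."""
    masks = []
    for channel in (tumor_channel, leukocyte_channel):
        smoothed = preprocess_channel(image, channel)
        model = multi_otsu(smoothed, n_classes=4, channel=channel)
        masks.append(region_mask_from_channel(smoothed, model))
    return tumor_stroma(masks[0], masks[1])


def assign_region(
    cell_table: CellTable, region_masks: RegionMasks, pixel_size_um: float
) -> CellTable:
    """Label each cell by its centroid pixel: intratumor, stroma, or none."""
    table = cell_table.copy()
    H, W = region_masks.tumor.shape
    rows = np.clip((table.df["y_um"] / pixel_size_um).astype(int), 0, H - 1)
    cols = np.clip((table.df["x_um"] / pixel_size_um).astype(int), 0, W - 1)
    in_tumor = region_masks.tumor[rows, cols]
    in_stroma = region_masks.stroma[rows, cols]
    region = np.where(in_tumor, "intratumor", np.where(in_stroma, "stroma", "none"))
    table.df["region"] = region
    return table


def two_means_split(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal 1D 2-means by scanning all sorted split points.

    Returns (threshold, positive mask): threshold is the mean of the upper
    (membership) cluster; positives are values >= threshold. All-identical
    input yields all-negative with a warning. Deterministic: no iterative
    initialization, the first minimal split wins.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.unique(values).size == 1:
        warnings.warn("all values identical; no membership cluster", stacklevel=2)
        return float("inf"), np.zeros(values.size, bool)
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = v.size
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cq = np.concatenate([[0.0], np.cumsum(v * v)])
    k = np.arange(1, n)  # lower cluster = v[:k]
    sse_lo = cq[k] - cs[k] ** 2 / k
    sse_hi = (cq[n] - cq[k]) - (cs[n] - cs[k]) ** 2 / (n - k)
    best = int(np.argmin(sse_lo + sse_hi)) + 1
    threshold = float((cs[n] - cs[best]) / (n - best))
    return threshold, values >= threshold


def classify_cells(
    cell_table: CellTable, channel: str
) -> tuple[np.ndarray, ThresholdModel]:
    """Positive/negative cell labels for one marker by exact 1D 2-means.

    Clusters per-cell log2(channel mean + 1); the threshold is the mean of
    the membership (upper) cluster, biasing against false positives.
    """
    col = f"mean_{channel}"
    if col not in cell_table.df.columns:
        raise KeyError(f"cell table lacks column {col!r}")
    logv = np.log2(cell_table.df[col].to_numpy(dtype=float) + 1.0)
    threshold, positive = two_means_split(logv)
    lower = logv[~positive]
    upper = logv[positive]
    means = [
        float(lower.mean()) if lower.size else float("nan"),
        float(upper.mean()) if upper.size else float("nan"),
    ]
    model = ThresholdModel(
        channel=channel,
        thresholds=np.array([threshold]),
        class_means=np.array(means),
    )
    return positive, model


def _upper_quartile_mean(values: np.ndarray) -> float:
    """Mean of values at or above their 75th percentile (linear interpolation)."""
    q75 = np.percentile(values, 75)
    return float(values[values >= q75].mean())


def call_loaded_macrophages(
    image: MarkerImage,
    mask: LabelMask,
    cell_table: CellTable,
    melanoma_channel: str,
    threshold_model: ThresholdModel,
    macrophage_type: str = "macrophage",
    membrane_width_px: int = 1,
) -> CellTable:
    """Flag antigen-loaded macrophages from cytoplasmic tumor signal.

    Cytoplasm is the cell minus its 1-px internal boundary; the per-cell
    statistic is the upper-quartile average of cytoplasmic tumor-marker
    intensity, and a macrophage is loaded when log2(statistic + 1) reaches
    the tumor-marker cell-labeling threshold. Cells with an empty cytoplasm
    get a missing flag and drop out of loaded/unloaded splits.
    """
    table = cell_table.copy()
    chan = image[melanoma_channel]
    threshold = float(threshold_model.thresholds[-1])
    loaded = np.full(len(table), None, dtype=object)
    is_mac = table.has_type(macrophage_type)
    for i, cid in enumerate(table.cell_ids):
        if not is_mac[i]:
            continue
        rr, cc = mask.pixels(int(cid))
        mem_r, mem_c = extract_membrane(mask, int(cid), membrane_width_px)
        cell = np.zeros(mask.shape, bool)
        cell[rr, cc] = True
        cell[mem_r, mem_c] = False
        cyto = chan[cell]
        if cyto.size == 0:
            loaded[i] = None  # tiny cell: excluded from loaded/unloaded splits
            continue
        stat = _upper_quartile_mean(cyto)
        loaded[i] = bool(np.log2(stat + 1.0) >= threshold)
    table.df["loaded"] = loaded
    return table
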