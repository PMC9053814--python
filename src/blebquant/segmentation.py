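"""Global auto-thresholding and binary cleanup.

Produces the whole-cell mask from an (edited) intensity stack: binarize with
a selectable histogram threshold, fill interior holes, open away attached
noise, and keep the cell by size exclusion.

Otsu is computed in-package as an exhaustive maximization of between-class
variance over a 256-bin histogram; the remaining methods delegate to
``skimage.filters``.  All methods operate on a 256-bin histogram regardless
of bit depth (intensities are rescaled to the frame's [min, max] range), so
results do not depend on camera bit depth.

Connectivity convention: 8-connected foreground, 4-connected background
(holes), the standard complementary pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters as _skf
from skimage import morphology
from skimage.measure import label as _sk_label

from .stack_io import ImageStack, MaskStack

logger = logging.getLogger(__name__)

THRESHOLD_METHODS = ("otsu", "mean", "li", "triangle", "yen", "isodata", "minimum")


@dataclass
class ThresholdReport:
    """Threshold values actually applied to a stack."""

    method: str
    mode: str  # "first_frame" or "per_frame"
    foreground_polarity: str  # "bright_cell" or "dark_cell"
    values: dict[int, float] = field(default_factory=dict)


def _histogram_256(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram over the frame's intensity range with bin centers."""
    lo = float(frame.min())
    hi = float(frame.max())
    counts, edges = np.histogram(frame.ravel(), bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(np.int64), centers


def _otsu_from_histogram(counts: np.ndarray, centers: np.ndarray) -> float:
    """Otsu threshold: maximize between-class variance over all cut points.

    The cut point after bin k assigns bins <= k to background.  Returns the
    center of the last background bin (the conventional "threshold at or
    below" value); ties resolve to the lowest cut.
    """
    counts = counts.astype(np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    cum_mean = np.cumsum(counts * centers)
    grand = cum_mean[-1]
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_mean / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (grand - cum_mean) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(between))
    return float(centers[k])


def auto_threshold(frame: np.ndarray, method: str = "otsu", frame_index: int | None = None) -> float:
    """Compute a global threshold for one frame.

    Foreground is every pixel strictly above the returned value.

    Parameters
    ----------
    frame : 2-D array
        Intensity image with at least two distinct values.
    method : one of ``otsu, mean, li, triangle, yen, isodata, minimum``
    frame_index : int, optional
        Used only to name the frame in error messages.

    Raises
    ------
    ValueError
        On a constant frame or unknown method.
    """
    frame = np.asarray(frame)
    where = f" (frame {frame_index})" if frame_index is not None else ""
    if frame.min() == frame.max():
        raise ValueError(f"cannot threshold a constant frame{where}")
    if method == "mean":
        return float(frame.mean())
    counts, centers = _histogram_256(frame)
    if method == "otsu":
        return _otsu_from_histogram(counts, centers)
    hist = (counts, centers)
    try:
        if method == "li":
            return float(_skf.threshold_li(frame))
        if method == "triangle":
            return float(_skf.threshold_triangle(frame, nbins=256))
        if method == "yen":
            return float(_skf.threshold_yen(hist=hist))
        if method == "isodata":
            return float(_skf.threshold_isodata(hist=hist))
        if method == "minimum":
            return float(_skf.threshold_minimum(hist=hist))
    except RuntimeError as exc:  # e.g. minimum: no two maxima
        raise ValueError(f"threshold method {method!r} failed{where}: {exc}") from exc
    raise ValueError(f"unknown threshold method {method!r}; choose from {THRESHOLD_METHODS}")


def binarize_stack(
    stack: ImageStack,
    method: str = "otsu",
    mode: str = "per_frame",
    polarity: str = "bright_cell",
) -> tuple[MaskStack, ThresholdReport]:
    """Threshold every frame of a stack.

    In ``first_frame`` mode the threshold computed on frame 0 is applied to
    all frames (the original workflow's preview-then-apply behaviour); in
    ``per_frame`` mode it is recomputed on each frame, which is robust to
    slow intensity drift over hours of imaging.

    ``dark_cell`` polarity selects pixels *below* the threshold instead.
    """
    if mode not in ("first_frame", "per_frame"):
        raise ValueError(f"mode must be 'first_frame' or 'per_frame', got {mode!r}")
    if polarity not in ("bright_cell", "dark_cell"):
        raise ValueError(f"polarity must be 'bright_cell' or 'dark_cell', got {polarity!r}")
    report = ThresholdReport(method=method, mode=mode, foreground_polarity=polarity)
    masks = np.empty(stack.frames.shape, dtype=bool)
    if mode == "first_frame":
        t0 = auto_threshold(stack.frames[0], method, frame_index=0)
        report.values[0] = t0
        thresholds = [t0] * stack.n_frames
    else:
        thresholds = []
        for t in range(stack.n_frames):
            tv = auto_threshold(stack.frames[t], method, frame_index=t)
            report.values[t] = tv
            thresholds.append(tv)
    for t, tv in enumerate(thresholds):
        if polarity == "bright_cell":
            masks[t] = stack.frames[t] > tv
        else:
            masks[t] = stack.frames[t] < tv
    return (
        MaskStack(
            masks,
            compartment="tracer",
            pixel_size_um=stack.pixel_size_um,
            frame_interval_min=stack.frame_interval_min,
            name=stack.name,
        ),
        report,
    )


def fill_holes(frame: np.ndarray) -> np.ndarray:
    """Set every background region not connected to the border to foreground.

    Hole connectivity is 4-neighbor (complement of the 8-connected
    foreground).  Idempotent.
    """
    return ndimage.binary_fill_holes(np.asarray(frame, dtype=bool))


def size_exclude(
    frame: np.ndarray,
    policy: str = "keep_largest",
    min_area_um2: float = 0.0,
    pixel_size_um: float = 1.0,
    frame_index: int | None = None,
) -> np.ndarray:
    """Remove background objects by size.

    ``keep_largest`` retains only the largest 8-connected component (ties to
    the lowest label in scan order); ``min_area`` removes components smaller
    than ``min_area_um2``.
    """
    frame = np.asarray(frame, dtype=bool)
    labels = _sk_label(frame, connectivity=2)
    n = labels.max()
    if n == 0:
        if policy == "keep_largest":
            where = f" (frame {frame_index})" if frame_index is not None else ""
            logger.warning("size_exclude: empty frame, nothing to keep%s", where)
        return frame.copy()
    areas = np.bincount(labels.ravel())[1:]  # component id k -> areas[k-1]
    if policy == "keep_largest":
        keep = int(np.argmax(areas)) + 1
        return labels == keep
    if policy == "min_area":
        min_px = min_area_um2 / pixel_size_um**2
        keep_ids = np.flatnonzero(areas >= min_px) + 1
        return np.isin(labels, keep_ids)
    raise ValueError(f"unknown size policy {policy!r}")


def remove_attached_noise(frame: np.ndarray, radius: int = 0) -> np.ndarray:
    """Morphological opening with a disk of the given pixel radius.

    Headless replacement for manually cutting noise objects attached to the
    cell outline.  ``radius=0`` is the identity; the operation is
    anti-extensive and idempotent.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    frame = np.asarray(frame, dtype=bool)
    if radius == 0:
        return frame.copy()
    return morphology.opening(frame, morphology.disk(radius))


def segment_whole_cell(
    stack: ImageStack,
    method: str = "otsu",
    mode: str = "per_frame",
    polarity: str = "bright_cell",
    fill: bool = True,
    open_radius: int = 0,
    size_policy: str = "keep_largest",
    min_area_um2: float = 0.0,
) -> tuple[MaskStack, MaskStack, ThresholdReport]:
    """Full segmentation: threshold, fill holes, open, size-exclude.

    Returns ``(whole_cell, raw_threshold_mask, report)``; the raw mask
    corresponds to the original workflow's intermediate "Threshold" stack.
    """
    raw, report = binarize_stack(stack, method=method, mode=mode, polarity=polarity)
    cleaned = np.empty_like(raw.frames)
    for t in range(raw.n_frames):
        frame = raw.frames[t]
        if fill:
            frame = fill_holes(frame)
        frame = remove_attached_noise(frame, open_radius)
        if fill and open_radius > 0:
            frame = fill_holes(frame)  # opening can re-expose interior holes
        frame = size_exclude(
            frame,
            policy=size_policy,
            min_area_um2=min_area_um2,
            pixel_size_um=stack.pixel_size_um,
            frame_index=t,
        )
        cleaned[t] = frame
    whole = MaskStack(
        cleaned,
        compartment="whole_cell",
        pixel_size_um=stack.pixel_size_um,
        frame_interval_min=stack.frame_interval_min,
        name=stack.name,
    )
    return whole, raw, report
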