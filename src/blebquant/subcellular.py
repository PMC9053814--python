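"""Mask algebra splitting the whole-cell mask into subcellular compartments.

The user-supplied cell-body outline is removed from the whole-cell mask to
leave only blebs; subtracting the blebs back from the whole cell gives the
cell body.  Per frame the three masks form an exact partition:

    cell_body ∪ all_blebs = whole_cell,   cell_body ∩ all_blebs = ∅

The largest bleb per frame (by area, ties broken to the lowest label in scan
order) is the per-frame proxy for the leader bleb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _sk_label

from .stack_io import MaskStack, RoiSet

logger = logging.getLogger(__name__)


@dataclass
class LabeledFrame:
    """Connected-component labelling of one all-blebs frame.

    ``labels`` is 0 for background and k >= 1 for the k-th 8-connected
    component in scan order; ``areas_um2`` maps each id to its area.
    """

    labels: np.ndarray
    areas_um2: dict[int, float]

    @property
    def count(self) -> int:
        return len(self.areas_um2)


def _body_to_mask_stack(whole: MaskStack, body: RoiSet | MaskStack) -> MaskStack:
    if isinstance(body, RoiSet):
        return body.to_mask_stack(
            whole.n_frames,
            whole.shape,
            compartment="cell_body",
            pixel_size_um=whole.pixel_size_um,
            frame_interval_min=whole.frame_interval_min,
        )
    if body.frames.shape != whole.frames.shape:
        raise ValueError(
            f"body mask shape {body.frames.shape} does not match whole-cell "
            f"shape {whole.frames.shape}"
        )
    return body


def remove_body(whole: MaskStack, body: RoiSet | MaskStack) -> MaskStack:
    """All-blebs mask: whole-cell AND NOT body, per frame.

    The body may be given as polygon ROIs (rasterized; frames without a
    polygon inherit the nearest earlier one) or as a mask stack.  Body pixels
    outside the whole-cell mask are irrelevant (intersection semantics).  A
    body covering the entire whole-cell mask on every frame yields an empty
    all-blebs stack with a warning — a bleb-free cell, not an error.
    """
    body_masks = _body_to_mask_stack(whole, body)
    blebs = whole.frames & ~body_masks.frames
    if not blebs.any() and whole.frames.any():
        logger.warning(
            "%s: cell body covers the whole-cell mask on every frame "
            "(bleb-free cell)",
            whole.name,
        )
    return MaskStack(
        blebs,
        compartment="all_blebs",
        pixel_size_um=whole.pixel_size_um,
        frame_interval_min=whole.frame_interval_min,
        name=whole.name,
    )


def derive_cell_body(whole: MaskStack, all_blebs: MaskStack) -> MaskStack:
    """Cell body: whole-cell AND NOT all-blebs.

    Requires all_blebs ⊆ whole_cell per frame, so that the body and the
    blebs partition the whole cell exactly.
    """
    outside = all_blebs.frames & ~whole.frames
    if outside.any():
        bad = int(np.flatnonzero(outside.reshape(all_blebs.n_frames, -1).any(axis=1))[0])
        raise ValueError(
            f"all_blebs is not contained in whole_cell (first offending frame {bad})"
        )
    return MaskStack(
        whole.frames & ~all_blebs.frames,
        compartment="cell_body",
        pixel_size_um=whole.pixel_size_um,
        frame_interval_min=whole.frame_interval_min,
        name=whole.name,
    )


def label_blebs(
    frame: np.ndarray,
    pixel_size_um: float = 1.0,
    min_bleb_area_um2: float = 0.0,
) -> LabeledFrame:
    """Label the 8-connected blebs in one frame.

    Components smaller than ``min_bleb_area_um2`` are discarded before
    labelling (thresholding speckle can masquerade as blebs; the default
    keeps everything).  Ids are consecutive from 1 in scan order.
    """
    frame = np.asarray(frame, dtype=bool)
    labels = _sk_label(frame, connectivity=2)
    if labels.max() and min_bleb_area_um2 > 0:
        areas_px = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas_px * pixel_size_um**2 >= min_bleb_area_um2) + 1
        frame = np.isin(labels, keep)
        labels = _sk_label(frame, connectivity=2)
    areas_px = np.bincount(labels.ravel())[1:] if labels.max() else np.array([], dtype=int)
    areas = {k + 1: float(a * pixel_size_um**2) for k, a in enumerate(areas_px)}
    return LabeledFrame(labels=labels, areas_um2=areas)


def label_stack(all_blebs: MaskStack, min_bleb_area_um2: float = 0.0) -> list[LabeledFrame]:
    """:func:`label_blebs` applied to every frame of an all-blebs stack."""
    return [
        label_blebs(all_blebs.frames[t], all_blebs.pixel_size_um, min_bleb_area_um2)
        for t in range(all_blebs.n_frames)
    ]


def largest_bleb(
    all_blebs: MaskStack, labeled: list[LabeledFrame] | None = None
) -> MaskStack:
    """Keep only the maximum-area bleb on each frame.

    Bleb-free frames stay empty.  Area ties break to the lowest component id
    (deterministic scan order) and are logged.
    """
    if labeled is None:
        labeled = label_stack(all_blebs)
    out = np.zeros_like(all_blebs.frames)
    for t, lf in enumerate(labeled):
        if not lf.areas_um2:
            logger.info("%s: frame %d is bleb-free", all_blebs.name, t)
            continue
        best_area = max(lf.areas_um2.values())
        winners = sorted(k for k, a in lf.areas_um2.items() if a == best_area)
        if len(winners) > 1:
            logger.warning(
                "%s: frame %d has %d blebs tied at %.6g um^2; keeping label %d",
                all_blebs.name, t, len(winners), best_area, winners[0],
            )
        out[t] = lf.labels == winners[0]
    return MaskStack(
        out,
        compartment="largest_bleb",
        pixel_size_um=all_blebs.pixel_size_um,
        frame_interval_min=all_blebs.frame_interval_min,
        name=all_blebs.name,
    )
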