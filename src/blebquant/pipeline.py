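"""End-to-end orchestration: movie in, compartment stacks and tables out.

Mirrors the original plugin's workflow and file naming: the edited movie is
thresholded and cleaned into ``Whole_cell``, the user-supplied body outline
splits it into ``All_blebs`` and ``Cell_body``, the largest bleb per frame
becomes ``Largest_blebs``, and every stack gets a CSV of per-frame
measurements plus one summary row per cell.  Runs are deterministic: the
analysis path contains no randomness, and numbers are serialized with six
significant digits, so identical inputs give byte-identical outputs.

Supports restarting partway (from a saved whole-cell or all-blebs mask) and
analyzing multiple cells on one movie, each with its own body ROI set and
optional exclusion ROIs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    DEFAULT_DIR_MIN,
    DEFAULT_LEADER_AREA_FRAC,
    DEFAULT_LINK_MIN_OVERLAP,
    DEFAULT_PERSISTENCE_FRAMES,
    DEFAULT_SPEED_MIN_UM_MIN,
    BlebTrack,
    Phenotype,
    Trajectory,
    classify,
    instantaneous_speeds,
    track_blebs,
)
from .morphometrics import (
    CellSummary,
    ShapeRecord,
    measure,
    percent_areas,
    records_to_frame,
    summaries_to_frame,
    summarize_cell,
)
from .segmentation import binarize_stack, segment_whole_cell
from .stack_io import (
    ImageStack,
    MaskStack,
    RoiSet,
    apply_exclusions,
    load_mask_stack,
    load_rois,
    load_stack,
    write_mask_stack,
)
from .subcellular import (
    derive_cell_body,
    label_stack,
    largest_bleb,
    remove_body,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class CellConfig:
    """Per-cell inputs: identity, body outline, optional exclusions."""

    cell_id: str
    body_roi: str | None = None  # path to ROI file, or None when resuming later
    exclusion_roi: str | None = None


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    input_path: str
    output_dir: str
    run_name: str = "run"
    channel: int | None = None
    z_policy: int | str = "max_projection"
    axes: str | None = None
    pixel_size_um: float | None = None
    frame_interval_min: float | None = None
    threshold_method: str = "otsu"
    threshold_mode: str = "per_frame"
    polarity: str = "bright_cell"
    fill_holes: bool = True
    open_radius_px: int = 0
    size_policy: str = "keep_largest"
    min_area_um2: float = 0.0
    min_bleb_area_um2: float = 0.0
    report_all_methods: bool = False
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES
    leader_area_frac: float = DEFAULT_LEADER_AREA_FRAC
    speed_min_um_min: float = DEFAULT_SPEED_MIN_UM_MIN
    dir_min: float = DEFAULT_DIR_MIN
    link_min_overlap: float = DEFAULT_LINK_MIN_OVERLAP
    resume: str = "none"  # none | from_whole_cell | from_all_blebs
    cells: list[CellConfig] = field(default_factory=lambda: [CellConfig("cell1")])

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat TOML/JSON config; keyword overrides win."""
        path = Path(path)
        if path.suffix == ".json":
            raw = json.loads(path.read_text())
        else:
            import tomllib

            raw = tomllib.loads(path.read_text())
        cells = [CellConfig(**c) for c in raw.pop("cells", [])]
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if cells:
            cfg.cells = cells
        return cfg


@dataclass
class CellResult:
    """All outputs for one cell."""

    cell_id: str
    records: pd.DataFrame
    summary: CellSummary
    trajectory: Trajectory
    tracks: list[BlebTrack]
    phenotype: Phenotype
    masks: dict[str, MaskStack]


def analyze_cell(
    whole: MaskStack,
    body: RoiSet | MaskStack,
    cell_id: str = "cell",
    min_bleb_area_um2: float = 0.0,
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
    leader_area_frac: float = DEFAULT_LEADER_AREA_FRAC,
    speed_min_um_min: float = DEFAULT_SPEED_MIN_UM_MIN,
    dir_min: float = DEFAULT_DIR_MIN,
    link_min_overlap: float = DEFAULT_LINK_MIN_OVERLAP,
    all_blebs: MaskStack | None = None,
) -> CellResult:
    """Compartment split, morphometrics, tracking, and classification.

    ``all_blebs`` may be supplied directly (restart-partway); otherwise it
    is derived from the whole-cell mask and the body outline.
    """
    if all_blebs is None:
        all_blebs = remove_body(whole, body)
    cell_body = derive_cell_body(whole, all_blebs)
    labeled = label_stack(all_blebs, min_bleb_area_um2)
    largest = largest_bleb(all_blebs, labeled)

    px = whole.pixel_size_um
    records: list[ShapeRecord] = []
    centroids = []
    whole_areas = whole.areas_um2()
    for t in range(whole.n_frames):
        rec_whole = measure(whole.frames[t], px, t, "whole_cell")
        if rec_whole is None:
            logger.warning("%s: empty whole-cell mask on frame %d", cell_id, t)
            continue
        n_blebs = labeled[t].count
        total_bleb_area = float(sum(labeled[t].areas_um2.values()))
        rec_largest = measure(largest.frames[t], px, t, "largest_bleb")
        largest_area = rec_largest.area_um2 if rec_largest else 0.0
        pct_total, pct_leader = percent_areas(
            rec_whole.area_um2, total_bleb_area, largest_area
        )
        rec_whole.bleb_count = n_blebs
        rec_whole.pct_total_blebs = pct_total
        rec_whole.pct_leader_bleb = pct_leader
        records.append(rec_whole)
        centroids.append((rec_whole.centroid_x_um, rec_whole.centroid_y_um))

        rec_body = measure(cell_body.frames[t], px, t, "cell_body")
        if rec_body is not None:
            records.append(rec_body)

        rec_blebs = measure(all_blebs.frames[t], px, t, "all_blebs")
        if rec_blebs is not None:
            rec_blebs.bleb_count = n_blebs
            rec_blebs.pct_total_blebs = pct_total
            records.append(rec_blebs)
        else:
            # Bleb-free frame: count 0 and 0% of cell area, shape undefined.
            records.append(
                ShapeRecord(
                    frame=t, compartment="all_blebs",
                    area_um2=np.nan, perimeter_um=np.nan, circularity=np.nan,
                    roundness=np.nan, aspect_ratio=np.nan, solidity=np.nan,
                    centroid_x_um=np.nan, centroid_y_um=np.nan,
                    bleb_count=0, pct_total_blebs=0.0,
                )
            )
        if rec_largest is not None:
            rec_largest.bleb_count = n_blebs
            rec_largest.pct_leader_bleb = pct_leader
            records.append(rec_largest)

    traj = Trajectory(
        cell_id=cell_id,
        points_um=np.asarray(centroids).reshape(-1, 2),
        frame_interval_min=whole.frame_interval_min,
    )
    tracks = track_blebs(labeled, whole.frame_interval_min, link_min_overlap)
    phenotype = classify(
        traj, tracks, whole_areas,
        persistence_frames=persistence_frames,
        leader_area_frac=leader_area_frac,
        speed_min_um_min=speed_min_um_min,
        dir_min=dir_min,
    )
    df = records_to_frame(records)
    summary = summarize_cell(df, cell_id)
    masks = {
        "Whole_cell": whole,
        "All_blebs": all_blebs,
        "Cell_body": cell_body,
        "Largest_blebs": largest,
    }
    return CellResult(cell_id, df, summary, traj, tracks, phenotype, masks)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _trajectory_frame(result: CellResult) -> pd.DataFrame:
    traj = result.trajectory
    speeds = instantaneous_speeds(traj) if traj.n_points >= 2 else np.empty(0)
    return pd.DataFrame(
        {
            "frame": np.arange(traj.n_points),
            "t_min": np.arange(traj.n_points) * traj.frame_interval_min,
            "x_um": traj.points_um[:, 0],
            "y_um": traj.points_um[:, 1],
            "speed_um_min": np.concatenate([[np.nan], speeds])
            if traj.n_points >= 2
            else np.full(traj.n_points, np.nan),
        }
    )


def _tracks_frame(result: CellResult) -> pd.DataFrame:
    rows = []
    for track in result.tracks:
        for t in track.frames:
            rows.append(
                {
                    "track_id": track.track_id,
                    "frame": t,
                    "component_id": track.components[t],
                    "area_um2": track.areas_um2[t],
                    "lifetime_frames": track.lifetime_frames,
                    "lifetime_min": track.lifetime_min,
                }
            )
    cols = ["track_id", "frame", "component_id", "area_um2", "lifetime_frames", "lifetime_min"]
    return pd.DataFrame(rows, columns=cols)


def run(config: RunConfig) -> dict[str, CellResult]:
    """Execute the full pipeline for every configured cell.

    A failure in one cell aborts that cell with a logged reason; other
    cells continue.  Returns the per-cell results keyed by cell id.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / f"{config.run_name}_run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("blebquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_inner(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, out: Path) -> dict[str, CellResult]:
    logger.info("blebquant %s starting run %r", __version__, config.run_name)
    logger.info("parameters: %s", {k: v for k, v in vars(config).items() if k != "cells"})

    stack: ImageStack | None = None
    if config.resume == "none" or config.resume == "from_whole_cell":
        pass
    if config.resume == "none":
        stack = load_stack(
            config.input_path,
            channel=config.channel,
            z_policy=config.z_policy,
            axes=config.axes,
        )
        if config.pixel_size_um and config.frame_interval_min:
            from .stack_io import calibrate

            stack = calibrate(stack, config.pixel_size_um, config.frame_interval_min)

    results: dict[str, CellResult] = {}
    summaries: list[CellSummary] = []
    pheno_rows = []
    for cell in config.cells:
        try:
            result = _run_cell(config, out, stack, cell)
        except Exception:
            logger.exception("cell %s failed; continuing with remaining cells", cell.cell_id)
            continue
        results[cell.cell_id] = result
        summaries.append(result.summary)
        pheno_rows.append(
            {
                "cell_id": cell.cell_id,
                "label": result.phenotype.label,
                "has_leader_bleb": result.phenotype.has_leader_bleb,
                "is_mobile": result.phenotype.is_mobile,
                **result.phenotype.parameters,
            }
        )

    if summaries:
        _write_csv(summaries_to_frame(summaries), out / f"{config.run_name}_summary.csv")
        _write_csv(pd.DataFrame(pheno_rows), out / f"{config.run_name}_phenotypes.csv")
    logger.info("run %r finished: %d/%d cells analyzed", config.run_name, len(results), len(config.cells))
    return results


def _run_cell(
    config: RunConfig,
    out: Path,
    stack: ImageStack | None,
    cell: CellConfig,
) -> CellResult:
    prefix = f"{config.run_name}_{cell.cell_id}"
    logger.info("analyzing cell %s", cell.cell_id)

    whole: MaskStack | None = None
    all_blebs: MaskStack | None = None
    if config.resume == "from_whole_cell":
        whole = load_mask_stack(out / f"{prefix}_Whole_cell.tif", "whole_cell")
        logger.info("resumed %s from saved Whole_cell mask", cell.cell_id)
    elif config.resume == "from_all_blebs":
        whole = load_mask_stack(out / f"{prefix}_Whole_cell.tif", "whole_cell")
        all_blebs = load_mask_stack(out / f"{prefix}_All_blebs.tif", "all_blebs")
        logger.info("resumed %s from saved All_blebs mask", cell.cell_id)
    else:
        assert stack is not None
        edited = stack
        if cell.exclusion_roi:
            edited = apply_exclusions(stack, load_rois(cell.exclusion_roi))
            logger.info("applied exclusion ROIs for %s", cell.cell_id)
        if config.report_all_methods:
            _report_all_methods(edited, out, prefix)
        whole, raw, report = segment_whole_cell(
            edited,
            method=config.threshold_method,
            mode=config.threshold_mode,
            polarity=config.polarity,
            fill=config.fill_holes,
            open_radius=config.open_radius_px,
            size_policy=config.size_policy,
            min_area_um2=config.min_area_um2,
        )
        write_mask_stack(raw, out / f"{prefix}_Threshold_{config.threshold_method}.tif")
        _write_csv(
            pd.DataFrame(
                {"frame": list(report.values), "method": report.method, "value": list(report.values.values())}
            ),
            out / f"{prefix}_threshold_report.csv",
        )

    body: RoiSet | MaskStack
    if all_blebs is not None:
        body = derive_cell_body(whole, all_blebs)  # only for the masks dict
    elif cell.body_roi:
        body_path = Path(cell.body_roi)
        if body_path.suffix.lower() in (".tif", ".tiff"):
            body = load_mask_stack(body_path, "cell_body")
        else:
            body = load_rois(body_path, cell_id=cell.cell_id)
    else:
        raise ValueError(f"cell {cell.cell_id}: body_roi is required unless resuming from all_blebs")

    result = analyze_cell(
        whole,
        body,
        cell_id=cell.cell_id,
        min_bleb_area_um2=config.min_bleb_area_um2,
        persistence_frames=config.persistence_frames,
        leader_area_frac=config.leader_area_frac,
        speed_min_um_min=config.speed_min_um_min,
        dir_min=config.dir_min,
        link_min_overlap=config.link_min_overlap,
        all_blebs=all_blebs,
    )

    for mask_name, mask in result.masks.items():
        write_mask_stack(mask, out / f"{prefix}_{mask_name}.tif")
    _write_csv(result.records, out / f"{prefix}_measurements.csv")
    _write_csv(_trajectory_frame(result), out / f"{prefix}_trajectory.csv")
    _write_csv(_tracks_frame(result), out / f"{prefix}_tracks.csv")
    logger.info(
        "cell %s: phenotype %s (leader=%s, mobile=%s)",
        cell.cell_id,
        result.phenotype.label,
        result.phenotype.has_leader_bleb,
        result.phenotype.is_mobile,
    )
    return result


def _report_all_methods(stack: ImageStack, out: Path, prefix: str) -> None:
    """Write every method's frame-0 mask for offline threshold choice."""
    from .segmentation import THRESHOLD_METHODS, auto_threshold
    import tifffile

    for method in THRESHOLD_METHODS:
        try:
            tv = auto_threshold(stack.frames[0], method, frame_index=0)
        except ValueError as exc:
            logger.warning("method %s failed on frame 0: %s", method, exc)
            continue
        mask = (stack.frames[0] > tv).astype(np.uint8) * 255
        tifffile.imwrite(str(out / f"{prefix}_preview_{method}.tif"), mask)
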