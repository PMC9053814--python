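"""Image-stack and ROI input/output.

Reads multi-dimensional TIFF time-lapses, reduces them to a single-channel,
single-Z time series, attaches physical calibration (micrometres per pixel,
minutes per frame), and handles the polygon ROIs that stand in for the
interactive "circle the cell body" step of the original workflow.

Coordinate convention: pixel coordinates are 0-based ``(row, col)``.
Polygon containment uses the even-odd rule and includes boundary pixels.
"""

from __future__ import annotations

import json
import logging
import struct
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import polygon as _sk_polygon
from skimage.draw import polygon_perimeter as _sk_polygon_perimeter

logger = logging.getLogger(__name__)

#: Fallback calibration for uncalibrated stacks.  1 µm/pixel is the identity
#: scale; 8 min/frame is the sampling interval implied by the reference
#: "5 frames = 40 minutes" persistence rule used throughout the dynamics code.
DEFAULT_PIXEL_SIZE_UM = 1.0
DEFAULT_FRAME_INTERVAL_MIN = 8.0

COMPARTMENTS = ("whole_cell", "cell_body", "all_blebs", "largest_bleb", "tracer")


@dataclass
class ImageStack:
    """A calibrated grayscale time series.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity data, any integer or float dtype.
    pixel_size_um : float
        Micrometres per pixel (> 0).
    frame_interval_min : float
        Minutes between consecutive frames (> 0).
    name : str
        Identifier used in output file names.
    calibrated : bool
        False when calibration was defaulted rather than supplied.
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    name: str = "stack"
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("pixel_size_um and frame_interval_min must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape (H, W)."""
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MaskStack:
    """Per-frame binary masks for one subcellular compartment."""

    frames: np.ndarray
    compartment: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    name: str = "mask"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames).astype(bool)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def areas_um2(self) -> np.ndarray:
        """Per-frame foreground area in µm²."""
        px = self.frames.reshape(self.n_frames, -1).sum(axis=1)
        return px * self.pixel_size_um**2


@dataclass
class RoiSet:
    """Polygon ROIs keyed by frame index.

    Frames without an explicit polygon inherit the nearest *earlier* polygon,
    mirroring how a user circling the cell body would keep the previous
    outline while the cell is static.
    """

    polygons: dict[int, np.ndarray] = field(default_factory=dict)
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        cleaned: dict[int, np.ndarray] = {}
        for frame, verts in self.polygons.items():
            arr = np.asarray(verts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValueError(
                    f"polygon for frame {frame} must be an (N>=3, 2) vertex list"
                )
            cleaned[int(frame)] = arr
        if not cleaned:
            raise ValueError("RoiSet requires at least one polygon")
        if min(cleaned) < 0:
            raise ValueError("frame indices must be non-negative")
        self.polygons = cleaned

    def polygon_for(self, frame: int) -> np.ndarray:
        """Polygon for ``frame``, falling back to the nearest earlier one."""
        if frame in self.polygons:
            return self.polygons[frame]
        earlier = [f for f in self.polygons if f < frame]
        if not earlier:
            # No earlier polygon: inherit the earliest available one.
            src = min(self.polygons)
        else:
            src = max(earlier)
        return self.polygons[src]

    def to_mask_stack(
        self,
        n_frames: int,
        shape: tuple[int, int],
        compartment: str = "cell_body",
        pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
        frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    ) -> MaskStack:
        """Rasterize the ROI set onto an image grid, one mask per frame."""
        frames = np.zeros((n_frames,) + tuple(shape), dtype=bool)
        for t in range(n_frames):
            frames[t] = rasterize_polygon(self.polygon_for(t), shape)
        return MaskStack(
            frames,
            compartment=compartment,
            pixel_size_um=pixel_size_um,
            frame_interval_min=frame_interval_min,
            name=self.cell_id,
        )


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed polygon given as (row, col) vertices.

    Interior pixels by the even-odd rule plus the boundary trace, so pixels
    the outline passes through count as inside.
    """
    verts = np.asarray(vertices, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _sk_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask[rr, cc] = True
    rr, cc = _sk_polygon_perimeter(
        np.round(verts[:, 0]).astype(int),
        np.round(verts[:, 1]).astype(int),
        shape=shape,
        clip=True,
    )
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# TIFF reading


def _squeeze_to_axes(data: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    """Drop singleton axes not in TCZYX and normalize axis labels."""
    axes = axes.upper().replace("S", "C").replace("Q", "T").replace("I", "T")
    keep = []
    for i, ax in enumerate(axes):
        if ax in "TCZYX" and not (data.shape[i] == 1 and ax not in "YX"):
            keep.append(i)
        elif ax in "YX":
            keep.append(i)
    data = data.reshape([data.shape[i] for i in keep])
    axes = "".join(axes[i] for i in keep)
    return data, axes


def load_stack(
    path: str | Path,
    channel: int | None = None,
    z_policy: int | str = "max_projection",
    axes: str | None = None,
    name: str | None = None,
) -> ImageStack:
    """Read a TIFF time-lapse and reduce it to a (T, H, W) intensity stack.

    Parameters
    ----------
    path : path
        Single- or multi-page TIFF.
    channel : int, optional
        Channel to keep when a C axis is present.  Required for
        multi-channel files.
    z_policy : int or {"max_projection", "mean_projection"}
        How to collapse a Z axis: an integer selects that slice, the named
        policies project across slices.  Ignored when no Z axis exists.
    axes : str, optional
        Explicit axis order (e.g. ``"TZYX"``) overriding file metadata.
        Required when the metadata is ambiguous for >3-D data.
    name : str, optional
        Stack name; defaults to the file stem.

    Returns
    -------
    ImageStack
        Time-ordered single-plane stack.  Calibration is taken from TIFF
        resolution/ImageJ metadata when present, otherwise defaulted with a
        warning and ``calibrated=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes
        pixel_size, frame_interval = _read_calibration(tf)

    if axes is not None:
        if len(axes) != data.ndim:
            raise ValueError(
                f"--axes {axes!r} has {len(axes)} letters but data has "
                f"{data.ndim} dimensions"
            )
        file_axes = axes
    data, file_axes = _squeeze_to_axes(data, file_axes)

    if data.ndim == 2:
        data = data[None]
        file_axes = "T" + file_axes if "T" not in file_axes else file_axes
    elif data.ndim == 3 and not set(file_axes) <= {"T", "Y", "X"}:
        pass  # C or Z axis present, handled below
    elif data.ndim > 3 and axes is None and not set(file_axes) <= {"T", "C", "Z", "Y", "X"}:
        raise ValueError(
            f"ambiguous axis order {file_axes!r} for {path.name}; pass axes= explicitly"
        )

    if data.ndim == 3 and set(file_axes) <= {"Y", "X", "T"}:
        stack = data
    else:
        # Reorder to TCZYX, inserting singleton axes for the missing ones.
        order = "TCZYX"
        for ax in order:
            if ax not in file_axes:
                data = data[None]
                file_axes = ax + file_axes
        perm = [file_axes.index(ax) for ax in order]
        data = np.transpose(data, perm)  # (T, C, Z, Y, X)

        n_c, n_z = data.shape[1], data.shape[2]
        if n_c > 1:
            if channel is None:
                raise ValueError(
                    f"{path.name} has {n_c} channels; pass channel= to select one"
                )
            if not 0 <= channel < n_c:
                raise IndexError(f"channel {channel} out of range [0, {n_c})")
            data = data[:, channel]
        else:
            data = data[:, 0]

        if n_z > 1:
            if isinstance(z_policy, (int, np.integer)):
                if not 0 <= z_policy < n_z:
                    raise IndexError(f"z slice {z_policy} out of range [0, {n_z})")
                data = data[:, z_policy]
            elif z_policy == "max_projection":
                data = data.max(axis=1)
            elif z_policy == "mean_projection":
                data = data.mean(axis=1)
            else:
                raise ValueError(f"unknown z_policy {z_policy!r}")
        else:
            data = data[:, 0]
        stack = data

    if stack.shape[0] < 1:
        raise ValueError(f"{path.name} contains zero frames")

    calibrated = pixel_size is not None and frame_interval is not None
    if not calibrated:
        logger.warning(
            "%s has no complete calibration metadata; defaulting to "
            "%g um/pixel, %g min/frame",
            path.name,
            DEFAULT_PIXEL_SIZE_UM,
            DEFAULT_FRAME_INTERVAL_MIN,
        )
    return ImageStack(
        stack,
        pixel_size_um=pixel_size if pixel_size else DEFAULT_PIXEL_SIZE_UM,
        frame_interval_min=frame_interval if frame_interval else DEFAULT_FRAME_INTERVAL_MIN,
        name=name or path.stem,
        calibrated=calibrated,
    )


def _read_calibration(tf: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Pixel size (µm) and frame interval (min) from TIFF metadata, if any."""
    pixel_size = None
    frame_interval = None
    meta = tf.imagej_metadata or {}
    page = tf.pages[0]
    res = page.tags.get("XResolution")
    unit = (meta.get("unit") or "").lower()
    if res is not None and unit in ("um", "micron", "micrometer", "µm"):
        num, den = res.value
        if num:
            pixel_size = den / num
    if "finterval" in meta and meta["finterval"]:
        # ImageJ stores the frame interval in seconds.
        frame_interval = float(meta["finterval"]) / 60.0
    return pixel_size, frame_interval


def calibrate(
    stack: ImageStack, pixel_size_um: float, frame_interval_min: float
) -> ImageStack:
    """Return a copy of ``stack`` with explicit physical calibration."""
    if pixel_size_um <= 0 or frame_interval_min <= 0:
        raise ValueError("pixel_size_um and frame_interval_min must be > 0")
    return replace(
        stack,
        pixel_size_um=float(pixel_size_um),
        frame_interval_min=float(frame_interval_min),
        calibrated=True,
    )


# ---------------------------------------------------------------------------
# ROI reading


def load_rois(path: str | Path, cell_id: str | None = None) -> RoiSet:
    """Load polygon ROIs from JSON, an ImageJ ``.roi`` file, or a ``.zip``.

    The JSON format is ``{"cell_id": ..., "frames": [{"frame": t,
    "vertices": [[r, c], ...]}, ...]}``.  ImageJ ROIs use their stored
    position (1-based T position, falling back to file order in a zip).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        return _load_rois_json(path, cell_id)
    if suffix == ".roi":
        frame, verts = _parse_imagej_roi(path.read_bytes())
        return RoiSet({frame: verts}, cell_id=cell_id or path.stem)
    if suffix == ".zip":
        polygons: dict[int, np.ndarray] = {}
        with zipfile.ZipFile(path) as zf:
            for i, info in enumerate(sorted(zf.namelist())):
                if not info.lower().endswith(".roi"):
                    continue
                frame, verts = _parse_imagej_roi(zf.read(info))
                polygons[frame if frame not in polygons else i] = verts
        if not polygons:
            raise ValueError(f"no .roi entries found in {path.name}")
        return RoiSet(polygons, cell_id=cell_id or path.stem)
    raise ValueError(f"unsupported ROI file type {suffix!r}")


def _load_rois_json(path: Path, cell_id: str | None) -> RoiSet:
    with open(path) as fh:
        payload = json.load(fh)
    if not payload or "frames" not in payload or not payload["frames"]:
        raise ValueError(f"{path.name} contains no polygons")
    polygons = {
        int(entry["frame"]): np.asarray(entry["vertices"], dtype=float)
        for entry in payload["frames"]
    }
    return RoiSet(polygons, cell_id=cell_id or payload.get("cell_id", path.stem))


def _parse_imagej_roi(buf: bytes) -> tuple[int, np.ndarray]:
    """Decode an ImageJ .roi polygon/freehand/trace outline.

    Only the fields needed for polygon outlines are decoded: header magic
    ``Iout``, ROI type, bounding box, vertex count, and the 1-based T
    position when set.
    """
    if len(buf) < 64 or buf[:4] != b"Iout":
        raise ValueError("not an ImageJ .roi file")
    roi_type = buf[6]
    top, left = struct.unpack(">hh", buf[8:12])
    n = struct.unpack(">H", buf[16:18])[0]
    # types: 0 polygon, 3 freehand, 4 traced
    if roi_type not in (0, 3, 4) or n < 3:
        raise ValueError(f"unsupported ROI type {roi_type} (need a polygon outline)")
    xs = np.frombuffer(buf, dtype=">h", count=n, offset=64).astype(float)
    ys = np.frombuffer(buf, dtype=">h", count=n, offset=64 + 2 * n).astype(float)
    t_position = struct.unpack(">i", buf[44:48])[0]  # 1-based, 0 = unset
    frame = max(t_position - 1, 0)
    verts = np.column_stack([ys + top, xs + left])
    return frame, verts


# ---------------------------------------------------------------------------
# Mask writing / reading


def write_mask_stack(mask: MaskStack, path: str | Path) -> Path:
    """Write a mask stack as an 8-bit binary TIFF (0/255), one page per frame."""
    path = Path(path)
    data = np.where(mask.frames, np.uint8(255), np.uint8(0))
    resolution = 1.0 / mask.pixel_size_um
    tifffile.imwrite(
        str(path),
        data,
        resolution=(resolution, resolution),
        metadata={
            "unit": "um",
            "finterval": mask.frame_interval_min * 60.0,
            "axes": "TYX",
        },
        imagej=True,
    )
    return path


def load_mask_stack(path: str | Path, compartment: str) -> MaskStack:
    """Read a binary TIFF written by :func:`write_mask_stack`."""
    stack = load_stack(path)
    return MaskStack(
        stack.frames > 0,
        compartment=compartment,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_min=stack.frame_interval_min,
        name=stack.name,
    )


def apply_exclusions(stack: ImageStack, exclusions: RoiSet) -> ImageStack:
    """Erase debris/other cells before thresholding ("tracer" editing).

    The interior of each exclusion polygon is replaced with the frame's modal
    background value so global thresholds are unaffected by the erased
    objects.
    """
    frames = stack.frames.copy()
    for t in range(stack.n_frames):
        mask = rasterize_polygon(exclusions.polygon_for(t), stack.shape)
        if not mask.any():
            continue
        frame = frames[t]
        vals, counts = np.unique(frame[~mask], return_counts=True)
        modal = vals[np.argmax(counts)] if vals.size else 0
        frame[mask] = modal
    return replace(stack, frames=frames)
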