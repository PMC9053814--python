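"""Cell trajectories, bleb tracking, and phenotype classification.

A confined blebbing cell falls into one of three phenotypes:

* **LM** (leader mobile) — forms a leader bleb and migrates,
* **LNM** (leader non-mobile) — forms a leader bleb but does not migrate,
* **NL** (no leader) — forms only small transient blebs and does not migrate.

Both predicates are persistence rules over a 5-frame (40 min at the
reference 8 min/frame sampling) window:

* *has_leader_bleb* — some bleb track survives ≥ ``persistence_frames``
  frames with mean area ≥ ``leader_area_frac`` of the mean whole-cell area
  over the same frames.
* *is_mobile* — some window of ``persistence_frames`` consecutive intervals
  has mean speed ≥ ``speed_min`` (µm/min) and a directionality ratio (net
  displacement / path length) ≥ ``dir_min``.

Bleb identity across frames uses greedy pixel-overlap linking: at this
sampling rate blebs appear and disappear between frames, so curvature-based
tracking is not applicable and no gap closing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .subcellular import LabeledFrame

logger = logging.getLogger(__name__)

#: Reference persistence rule: 5 frames at 8 min/frame = 40 minutes.
DEFAULT_PERSISTENCE_FRAMES = 5
DEFAULT_LEADER_AREA_FRAC = 0.10
DEFAULT_SPEED_MIN_UM_MIN = 0.25
DEFAULT_DIR_MIN = 0.5
DEFAULT_LINK_MIN_OVERLAP = 0.5


@dataclass
class Trajectory:
    """Whole-cell centroid track in physical units."""

    cell_id: str
    points_um: np.ndarray  # (T, 2) as (x, y)
    frame_interval_min: float

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float).reshape(-1, 2)
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")

    @property
    def n_points(self) -> int:
        return int(self.points_um.shape[0])


@dataclass
class BlebTrack:
    """One bleb identity linked across consecutive frames."""

    track_id: int
    components: dict[int, int]  # frame -> component id in that frame's labelling
    areas_um2: dict[int, float]  # frame -> area
    frame_interval_min: float

    @property
    def frames(self) -> list[int]:
        return sorted(self.components)

    @property
    def lifetime_frames(self) -> int:
        return len(self.components)

    @property
    def lifetime_min(self) -> float:
        return self.lifetime_frames * self.frame_interval_min

    @property
    def mean_area_um2(self) -> float:
        return float(np.mean(list(self.areas_um2.values())))


@dataclass
class Phenotype:
    label: str  # LM | LNM | NL | undetermined
    has_leader_bleb: bool
    is_mobile: bool
    parameters: dict = field(default_factory=dict)


def instantaneous_speeds(traj: Trajectory) -> np.ndarray:
    """Per-interval speeds |Δp| / Δt in µm/min; empty with < 2 points."""
    if traj.n_points < 2:
        logger.warning("%s: fewer than 2 trajectory points, no speeds", traj.cell_id)
        return np.empty(0)
    steps = np.diff(traj.points_um, axis=0)
    return np.hypot(steps[:, 0], steps[:, 1]) / traj.frame_interval_min


def top_speed(traj: Trajectory) -> float:
    """Maximum instantaneous speed (µm/min); 0 for degenerate trajectories."""
    speeds = instantaneous_speeds(traj)
    return float(speeds.max()) if speeds.size else 0.0


def zero_origin(traj: Trajectory) -> Trajectory:
    """Translate so the first point sits at the origin (plot-of-origin view)."""
    if traj.n_points == 0:
        return traj
    return replace(traj, points_um=traj.points_um - traj.points_um[0])


def track_blebs(
    labeled: list[LabeledFrame],
    frame_interval_min: float,
    link_min_overlap: float = DEFAULT_LINK_MIN_OVERLAP,
) -> list[BlebTrack]:
    """Link blebs across frames by greedy maximum pixel overlap.

    Candidate pairs (component i at frame t, component j at t+1) are ranked
    by overlap pixel count and matched greedily, each component at most
    once, subject to ``overlap / min(area_i, area_j) >= link_min_overlap``.
    Unmatched components start new tracks; tracks end when unmatched.  No
    gap closing: a bleb absent for one frame and back the next is two
    tracks, because at minutes-per-frame sampling blebs genuinely retract
    and reform between frames.
    """
    tracks: list[BlebTrack] = []
    active: dict[int, BlebTrack] = {}  # component id in previous frame -> track
    for t, lf in enumerate(labeled):
        new_active: dict[int, BlebTrack] = {}
        if t > 0 and active and lf.areas_um2:
            prev = labeled[t - 1]
            pairs = _overlap_pairs(prev, lf)
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for overlap_px, i, j in pairs:
                if i in used_prev or j in used_cur or i not in active:
                    continue
                area_i_px = np.count_nonzero(prev.labels == i)
                area_j_px = np.count_nonzero(lf.labels == j)
                if overlap_px / min(area_i_px, area_j_px) < link_min_overlap:
                    continue
                track = active[i]
                track.components[t] = j
                track.areas_um2[t] = lf.areas_um2[j]
                new_active[j] = track
                used_prev.add(i)
                used_cur.add(j)
        for j, area in lf.areas_um2.items():
            if j not in new_active:
                track = BlebTrack(
                    track_id=len(tracks),
                    components={t: j},
                    areas_um2={t: area},
                    frame_interval_min=frame_interval_min,
                )
                tracks.append(track)
                new_active[j] = track
        active = new_active
    return tracks


def _overlap_pairs(prev: LabeledFrame, cur: LabeledFrame) -> list[tuple[int, int, int]]:
    """(overlap_px, prev_id, cur_id) sorted by overlap desc, ids asc for ties."""
    both = (prev.labels > 0) & (cur.labels > 0)
    if not both.any():
        return []
    pi = prev.labels[both].astype(np.int64)
    ci = cur.labels[both].astype(np.int64)
    n_cur = cur.labels.max() + 1
    combo = pi * n_cur + ci
    counts = np.bincount(combo)
    pairs = []
    for idx in np.flatnonzero(counts):
        pairs.append((int(counts[idx]), int(idx // n_cur), int(idx % n_cur)))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    return pairs


def _has_leader_bleb(
    tracks: list[BlebTrack],
    whole_areas_um2: np.ndarray,
    persistence_frames: int,
    leader_area_frac: float,
) -> bool:
    for track in tracks:
        if track.lifetime_frames < persistence_frames:
            continue
        frames = track.frames
        mean_bleb = track.mean_area_um2
        mean_cell = float(np.mean(whole_areas_um2[frames]))
        if mean_cell > 0 and mean_bleb >= leader_area_frac * mean_cell:
            return True
    return False


def _is_mobile(
    traj: Trajectory,
    persistence_frames: int,
    speed_min: float,
    dir_min: float,
) -> bool:
    steps = np.diff(traj.points_um, axis=0)
    if len(steps) < persistence_frames:
        return False
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    w = persistence_frames
    for start in range(len(steps) - w + 1):
        window = steps[start : start + w]
        path = step_len[start : start + w].sum()
        if path == 0:
            continue
        mean_speed = path / (w * traj.frame_interval_min)
        net = float(np.hypot(*window.sum(axis=0)))
        if mean_speed >= speed_min and net / path >= dir_min:
            return True
    return False


def classify(
    traj: Trajectory,
    tracks: list[BlebTrack],
    whole_areas_um2: np.ndarray,
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
    leader_area_frac: float = DEFAULT_LEADER_AREA_FRAC,
    speed_min_um_min: float = DEFAULT_SPEED_MIN_UM_MIN,
    dir_min: float = DEFAULT_DIR_MIN,
) -> Phenotype:
    """Assign the LM / LNM / NL phenotype.

    Requires at least ``persistence_frames`` analyzed frames, otherwise the
    label is ``undetermined``.  The label follows directly from the two
    flags: LM = leader bleb and mobile, LNM = leader bleb only, NL = no
    leader bleb.
    """
    params = {
        "persistence_frames": persistence_frames,
        "leader_area_frac": leader_area_frac,
        "speed_min_um_min": speed_min_um_min,
        "dir_min": dir_min,
    }
    whole_areas_um2 = np.asarray(whole_areas_um2, dtype=float)
    if traj.n_points < persistence_frames:
        return Phenotype("undetermined", False, False, params)
    leader = _has_leader_bleb(tracks, whole_areas_um2, persistence_frames, leader_area_frac)
    mobile = _is_mobile(traj, persistence_frames, speed_min_um_min, dir_min)
    if leader and mobile:
        label = "LM"
    elif leader:
        label = "LNM"
    else:
        label = "NL"
    return Phenotype(label, leader, mobile, params)
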