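"""Myosin puncta dynamics from time-lapse movies.

MRLC-GFP accumulates in transient puncta on the migrating border cell
cluster; their lifetime (time from first appearance to complete
disappearance) is the dynamics statistic.  The chain is: per-frame spot
detection (same detector contract as the fixed-image puncta counter),
gapless greedy nearest-neighbour linking between consecutive frames, and
the lifetime convention n_frames_present * frame_interval — equivalently
first-absent minus first-present — so a punctum seen in a single 30 s
frame has a 30 s lifetime.

Tracks still present in the final frame are right-censored; tracks already
present in the first frame are left-censored.  Both are excluded from the
mean lifetime (their counts are reported), because their true lifetimes
are not observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import NoCompleteLifetimesError
from .imagequant import SpotDetection, detect_spots


@dataclass
class TimeLapse:
    """T x rows x cols intensity movie with the acquisition interval (s),
    pixel size (um/px) and the cluster mask within which puncta are
    scored."""

    frames: np.ndarray
    frame_interval_s: float = 30.0
    pixel_size_um: float = 0.2
    cluster_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (T, rows, cols) array with T >= 2")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")


@dataclass
class PunctumTrack:
    """Gapless trajectory of one punctum: present in the consecutive
    frames ``first_frame .. first_frame + len(centroids) - 1``."""

    first_frame: int
    centroids: List[Tuple[float, float]]
    censored: bool = False  # present in the movie's final frame
    left_censored: bool = False  # present in the movie's first frame
    lifetime_s: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return len(self.centroids)

    @property
    def frame_indices(self) -> range:
        return range(self.first_frame, self.first_frame + self.n_frames)


def detect_puncta_frame(
    frame: np.ndarray,
    cluster_mask: np.ndarray,
    threshold_k: float = 3.0,
    min_area_px: int = 4,
) -> List[SpotDetection]:
    """Per-frame spot detection inside the cluster mask; see
    :func:`folliquant.imagequant.detect_spots` for the detector contract."""
    return detect_spots(frame, cluster_mask, threshold_k, min_area_px)


def link_tracks(
    per_frame_detections: Sequence[List[SpotDetection]],
    max_link_dist_px: float = 4.0,
    max_gap: int = 0,
) -> List[PunctumTrack]:
    """Greedy nearest-neighbour linking of detections across consecutive
    frames.

    Candidate (track, detection) pairs within ``max_link_dist_px`` are
    assigned in order of increasing distance (ties by track creation order,
    then detection order; detections arrive in canonical centroid order).
    A track not matched in a frame terminates there — no gap closing with
    the default ``max_gap`` of 0, since a lifetime ends when the punctum
    has disappeared completely.  Unmatched detections open new tracks.
    Tracks reaching the final frame are marked censored; tracks starting in
    frame 0 are marked left-censored.
    """
    n_frames = len(per_frame_detections)
    tracks: List[PunctumTrack] = []
    # open tracks: (track index, frames since last seen)
    open_tracks: List[Tuple[int, int]] = []

    for t, detections in enumerate(per_frame_detections):
        candidates = []
        for slot, (ti, age) in enumerate(open_tracks):
            last = tracks[ti].centroids[-1]
            for di, det in enumerate(detections):
                dist = float(np.hypot(det.row - last[0], det.col - last[1]))
                if dist <= max_link_dist_px:
                    candidates.append((dist, slot, di))
        candidates.sort()
        used_slots, used_dets = set(), set()
        assignments = {}
        for dist, slot, di in candidates:
            if slot in used_slots or di in used_dets:
                continue
            used_slots.add(slot)
            used_dets.add(di)
            assignments[slot] = di

        next_open: List[Tuple[int, int]] = []
        for slot, (ti, age) in enumerate(open_tracks):
            if slot in assignments:
                det = detections[assignments[slot]]
                tracks[ti].centroids.append((det.row, det.col))
                next_open.append((ti, 0))
            elif age < max_gap:
                next_open.append((ti, age + 1))
        for di, det in enumerate(detections):
            if di not in used_dets:
                tracks.append(PunctumTrack(t, [(det.row, det.col)], left_censored=(t == 0)))
                next_open.append((len(tracks) - 1, 0))
        open_tracks = next_open

    for track in tracks:
        track.censored = track.first_frame + track.n_frames - 1 >= n_frames - 1
    return tracks


def compute_lifetimes(
    tracks: Sequence[PunctumTrack], frame_interval_s: float = 30.0
) -> Tuple[np.ndarray, float]:
    """Lifetimes (s) of fully observed tracks and their mean.

    Lifetime = number of frames present x frame interval.  Right- and
    left-censored tracks are excluded; if none remain the mean is
    undefined and :class:`NoCompleteLifetimesError` is raised.
    """
    complete = [t for t in tracks if not (t.censored or t.left_censored)]
    if not complete:
        raise NoCompleteLifetimesError("no complete lifetimes: all tracks censored")
    lifetimes = np.array([t.n_frames for t in complete], dtype=float) * frame_interval_s
    for track, life in zip(complete, lifetimes):
        track.lifetime_s = float(life)
    return lifetimes, float(lifetimes.mean())


def track_movie(
    movie: TimeLapse,
    threshold_k: float = 3.0,
    min_area_px: int = 4,
    max_link_dist_px: float = 4.0,
    max_gap: int = 0,
) -> List[PunctumTrack]:
    """Detect-and-link convenience wrapper over a whole movie."""
    per_frame = [
        detect_puncta_frame(frame, movie.cluster_mask, threshold_k, min_area_px)
        for frame in movie.frames
    ]
    return link_tracks(per_frame, max_link_dist_px, max_gap)
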