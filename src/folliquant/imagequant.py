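"""Fixed-image quantifications for follicle micrographs.

Implements the intensity measurements used on fixed, stained follicles:

* membrane line-profile ratios — the pMRLC intensity peak along a line
  drawn across a nurse-cell membrane, normalised to phalloidin (F-actin)
  intensity at the same point, three lines averaged per follicle, then
  normalised to the control-group average of the same experimental batch;
* the cluster/cytoplasm pMRLC ratio — mean pMRLC over the traced border
  cell cluster divided by the mean over an identically shaped region
  translated into nurse-cell cytoplasm;
* puncta count and maximum length on the cluster;
* migration index (border-cell distance / outer-follicle-cell distance,
  ~1 means on-time migration) and cluster length.

Coordinates are 0-based (row, col) pixel indices; physical distances are
reported in micrometres through the image pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import pdist
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import NoClusterError


@dataclass
class FollicleImage:
    """Registered multi-channel 2-D image: named channels sharing one
    shape, a pixel size in um/px, and optional named boolean masks
    (``cluster``, ``membranes``)."""

    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        self.shape = next(iter(shapes))
        for name, mask in self.masks.items():
            if mask.shape != self.shape:
                raise ValueError(f"mask {name!r} does not match image shape")


@dataclass
class LineProfileMeasurement:
    endpoints: tuple
    peak_pmrlc: float
    phalloidin_at_peak: float
    ratio: float


@dataclass
class ClusterMeasurement:
    cluster_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    mean_pmrlc_cluster: float
    mean_pmrlc_cytoplasm: float
    ratio: float


@dataclass
class FollicleGeometry:
    """Anterior-pole-referenced distances (um) for one Stage 9 follicle.

    ``border_cell_distance`` is measured to the front (or rear, if stated)
    of the border cell cluster; ``follicle_cell_distance`` to the anterior
    edge of the main-body (outer) follicle cells; ``cluster_front`` /
    ``cluster_rear`` bound the cluster along the migration axis.
    """

    border_cell_distance: float
    follicle_cell_distance: float
    follicle_length: float
    cluster_front: Optional[float] = None
    cluster_rear: Optional[float] = None

    def __post_init__(self):
        if not self.border_cell_distance > 0:
            raise ValueError("border_cell_distance must be > 0")
        if not 0 < self.follicle_cell_distance <= self.follicle_length:
            raise ValueError("follicle_cell_distance must be in (0, follicle_length]")
        if self.border_cell_distance > self.follicle_length:
            raise ValueError("border_cell_distance exceeds follicle_length")
        if self.cluster_front is not None and self.cluster_rear is not None:
            if self.cluster_rear > self.cluster_front:
                raise ValueError("cluster_rear must not exceed cluster_front")


@dataclass
class MigrationIndex:
    """Border-cell distance over outer-follicle-cell distance.  ~1 is
    on-time; <1 delayed; >1 accelerated."""

    value: float
    on_time_tolerance: float = 0.05

    @property
    def classification(self) -> str:
        if abs(self.value - 1.0) <= self.on_time_tolerance:
            return "on-time"
        return "delayed" if self.value < 1.0 else "accelerated"


@dataclass
class SpotDetection:
    row: float
    col: float
    area_px: int
    length_px: float
    peak: float


# ---------------------------------------------------------------------------
# line-profile membrane ratio


def _sample_profile(channel: np.ndarray, p0, p1) -> np.ndarray:
    """Bilinear samples along the segment p0->p1 at ~1 px spacing."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    rows = p0[0] + (p1[0] - p0[0]) * t
    cols = p0[1] + (p1[1] - p0[1]) * t
    return map_coordinates(channel, [rows, cols], order=1, mode="nearest")


def measure_membrane_ratio(
    image: FollicleImage,
    line: Tuple[tuple, tuple],
    smooth_window: int = 3,
    pmrlc_channel: str = "pmrlc",
    norm_channel: str = "phalloidin",
) -> LineProfileMeasurement:
    """Peak pMRLC along a membrane-crossing line, normalised to the
    normalisation channel at the same sample.

    Both channels are sampled at ~1 px spacing with linear interpolation
    and smoothed with a centred moving average of ``smooth_window``
    samples; the peak is the argmax of the smoothed pMRLC profile and the
    phalloidin value is read at that same index.
    """
    for name in (pmrlc_channel, norm_channel):
        if name not in image.channels:
            raise ValueError(f"channel {name!r} not present")
    (r0, c0), (r1, c1) = line
    nrow, ncol = image.shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= nrow - 1 and 0 <= c <= ncol - 1):
            raise ValueError("line endpoints must lie inside the image")

    pm = _sample_profile(image.channels[pmrlc_channel], (r0, c0), (r1, c1))
    ph = _sample_profile(image.channels[norm_channel], (r0, c0), (r1, c1))
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    if pm.size < smooth_window:
        raise ValueError("line shorter than the smoothing window")
    kernel = np.full(smooth_window, 1.0 / smooth_window)
    pm_s = np.convolve(pm, kernel, mode="valid")
    ph_s = np.convolve(ph, kernel, mode="valid")
    idx = int(np.argmax(pm_s))
    peak, at_peak = float(pm_s[idx]), float(ph_s[idx])
    if at_peak <= 0:
        raise ValueError("undefined ratio: normalisation channel is zero at the peak")
    return LineProfileMeasurement(((r0, c0), (r1, c1)), peak, at_peak, peak / at_peak)


def follicle_membrane_score(
    image: FollicleImage, lines: Sequence[Tuple[tuple, tuple]], smooth_window: int = 3
) -> float:
    """Arithmetic mean of exactly three membrane line-profile ratios.  Any
    failing line invalidates the follicle (the error propagates)."""
    if len(lines) != 3:
        raise ValueError("exactly 3 measurement lines are required per follicle")
    ratios = [measure_membrane_ratio(image, ln, smooth_window).ratio for ln in lines]
    return float(np.mean(ratios))


def normalize_to_control(scores, control_scores) -> np.ndarray:
    """Divide per-follicle scores by the mean of the control group from the
    same experimental batch (so the control's normalised mean is 1).
    Batches must be normalised independently, each against its own
    control, before pooling."""
    control = np.asarray(control_scores, dtype=float)
    if control.size == 0 or not control.mean() > 0:
        raise ValueError("control scores must be non-empty with positive mean")
    return np.asarray(scores, dtype=float) / control.mean()


# ---------------------------------------------------------------------------
# cluster / cytoplasm ratio


def cluster_pmrlc_ratio(
    image: FollicleImage,
    cluster_mask: Optional[np.ndarray] = None,
    cytoplasm_offset_px: Tuple[int, int] = (0, 0),
    pmrlc_channel: str = "pmrlc",
) -> ClusterMeasurement:
    """Mean pMRLC over the cluster mask divided by the mean over the same
    shape translated by ``cytoplasm_offset_px`` (rows, cols) into nurse-cell
    cytoplasm.  The translated mask must stay inside the image and off any
    supplied membrane mask."""
    mask = cluster_mask if cluster_mask is not None else image.masks.get("cluster")
    if mask is None or not mask.any():
        raise NoClusterError("no cluster")
    if mask.shape != image.shape:
        raise ValueError("cluster mask does not match image shape")
    dr, dc = cytoplasm_offset_px
    rows, cols = np.nonzero(mask)
    srows, scols = rows + int(dr), cols + int(dc)
    nrow, ncol = image.shape
    if srows.min() < 0 or scols.min() < 0 or srows.max() >= nrow or scols.max() >= ncol:
        raise ValueError("invalid cytoplasm placement: translated mask out of bounds")
    cyto_mask = np.zeros_like(mask)
    cyto_mask[srows, scols] = True
    membranes = image.masks.get("membranes")
    if membranes is not None and (cyto_mask & membranes).any():
        raise ValueError("invalid cytoplasm placement: overlaps membranes")
    channel = image.channels[pmrlc_channel]
    mean_cluster = float(channel[rows, cols].mean())
    mean_cyto = float(channel[srows, scols].mean())
    return ClusterMeasurement(mask, cyto_mask, mean_cluster, mean_cyto, mean_cluster / mean_cyto)


# ---------------------------------------------------------------------------
# puncta detection (shared with the time-lapse tracker)


def detect_spots(
    frame: np.ndarray,
    mask: np.ndarray,
    threshold_k: float = 3.0,
    min_area_px: int = 4,
    min_peak_k: float = 5.0,
) -> list:
    """Threshold-based spot detector restricted to a mask.

    Background is the median intensity over the mask; the robust SD is
    1.4826x the median absolute deviation.  Pixels strictly above
    background + ``threshold_k`` * robust SD form 8-connected components;
    components of at least ``min_area_px`` pixels whose peak also rises
    above background + ``min_peak_k`` * robust SD are spots (the peak
    prominence requirement suppresses counting-noise blobs that clear the
    area threshold by chance).  A spot's length is its Feret diameter
    (maximum pairwise pixel-centre distance, in px) and its centroid is
    background-subtracted intensity weighted.
    """
    if frame.shape != mask.shape:
        raise ValueError("frame and mask must share one shape")
    if not mask.any():
        raise NoClusterError("no cluster")
    vals = frame[mask]
    background = float(np.median(vals))
    robust_sd = 1.4826 * float(np.median(np.abs(vals - background)))
    hot = (frame > background + threshold_k * robust_sd) & mask

    detections = []
    for region in regionprops(cc_label(hot, connectivity=2)):
        if region.area < min_area_px:
            continue
        values = frame[region.coords[:, 0], region.coords[:, 1]]
        if values.max() <= background + min_peak_k * robust_sd:
            continue
        coords = region.coords.astype(float)
        weights = np.clip(values - background, 1e-12, None)
        centroid = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        length = float(pdist(coords).max()) if len(coords) > 1 else 0.0
        detections.append(
            SpotDetection(float(centroid[0]), float(centroid[1]), int(region.area), length, float(weights.max() + background))
        )
    # canonical order: by centroid, so downstream tie-breaks are
    # independent of labelling order
    detections.sort(key=lambda s: (s.row, s.col))
    return detections


def detect_fixed_puncta(
    image: FollicleImage,
    cluster_mask: Optional[np.ndarray] = None,
    threshold_k: float = 3.0,
    min_area_px: int = 4,
    pmrlc_channel: str = "pmrlc",
) -> Tuple[int, np.ndarray]:
    """Count pMRLC puncta on the border cell cluster and measure each
    punctum's maximum length in um.  Returns ``(count, lengths_um)``."""
    mask = cluster_mask if cluster_mask is not None else image.masks.get("cluster")
    if mask is None:
        raise NoClusterError("no cluster")
    detections = detect_spots(image.channels[pmrlc_channel], mask, threshold_k, min_area_px)
    lengths = np.array([d.length_px for d in detections]) * image.pixel_size_um
    return len(detections), lengths


# ---------------------------------------------------------------------------
# migration geometry


def migration_index(geom: FollicleGeometry) -> MigrationIndex:
    """Border-cell migration distance divided by outer-follicle-cell
    distance, both measured from the anterior pole."""
    if not geom.follicle_cell_distance > 0:
        raise ValueError("follicle_cell_distance must be > 0")
    return MigrationIndex(geom.border_cell_distance / geom.follicle_cell_distance)


def cluster_length(geom: FollicleGeometry) -> float:
    """Front-to-rear extent of the border cell cluster, in um."""
    if geom.cluster_front is None or geom.cluster_rear is None:
        raise ValueError("cluster_front and cluster_rear are required")
    return float(geom.cluster_front - geom.cluster_rear)
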