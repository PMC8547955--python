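"""Synthetic data with known ground truth for every pipeline stage.

The study's raw force curves and image stacks are not publicly deposited,
so each analysis stage is validated by parameter recovery on data
generated here: two-layer elastic indentation sweeps, two-channel
follicle scenes with membrane networks and a cluster region, time-lapses
of transient puncta with geometric (frame-grid exponential) lifetimes,
and follicle geometry tables.  Every generator takes an explicit seed and
is bit-for-bit reproducible; every generator returns the rendered data
together with a ground-truth table (a pandas DataFrame).

Layered contact is modelled with a depth-dependent apparent modulus: a
smooth logistic blend from the shallow (basement-membrane) modulus to the
deep (nurse-cell) modulus between ``blend_start_nm`` and ``blend_end_nm``.
This is a surrogate for full layered elasticity, calibrated so that
windowed Hertz fits on either side of the blend recover the set moduli;
the blend is saturated to within ~1% of the end members at its stated
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .afm import ForceCurve, ProbeModel, _cone_prefactor
from .dynamics import TimeLapse
from .imagequant import FollicleGeometry, FollicleImage

__all__ = [
    "TwoLayerSampleModel",
    "ProbeModel",
    "AcquisitionParams",
    "ImageSceneParams",
    "TimelapseParams",
    "region_mask",
    "apparent_modulus",
    "layered_cone_force",
    "simulate_force_curve",
    "simulate_afm_cohort",
    "simulate_follicle_image",
    "simulate_timelapse",
    "sample_lifetimes",
    "simulate_follicle_geometry",
]

# logistic scale such that the blend sits within 1% of either end member
# at blend_start / blend_end
_LOGISTIC_SATURATION = math.log(99.0)


def _require_finite(name, *values):
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"{name}: non-finite parameter {v!r}")


@dataclass(frozen=True)
class TwoLayerSampleModel:
    """Two-layer elastic sample: a stiff shallow shell (apparent modulus
    ``e_shallow_kpa`` governing small indentations) over a softer deep
    layer (``e_deep_kpa``), blended smoothly over
    [blend_start_nm, blend_end_nm]."""

    e_shallow_kpa: float
    e_deep_kpa: float
    blend_start_nm: float = 150.0
    blend_end_nm: float = 300.0
    poisson: float = 0.5

    def __post_init__(self):
        _require_finite(
            "TwoLayerSampleModel",
            self.e_shallow_kpa,
            self.e_deep_kpa,
            self.blend_start_nm,
            self.blend_end_nm,
            self.poisson,
        )
        if not (self.e_shallow_kpa > 0 and self.e_deep_kpa > 0):
            raise ValueError("moduli must be > 0")
        if not 0 <= self.blend_start_nm < self.blend_end_nm:
            raise ValueError("require 0 <= blend_start_nm < blend_end_nm")
        if not 0 <= self.poisson <= 0.5:
            raise ValueError("poisson must lie in [0, 0.5]")


@dataclass(frozen=True)
class AcquisitionParams:
    """Sweep acquisition: piezo step (nm), force ceiling (nN; follicle
    recordings used 1-5 nN), pre-contact travel (nm), additive Gaussian
    force noise SD (nN; None means 1% of the maximum force), and seed."""

    z_step_nm: float = 2.0
    max_force_nn: float = 3.0
    pre_contact_span_nm: float = 500.0
    force_noise_sd_nn: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        _require_finite(
            "AcquisitionParams", self.z_step_nm, self.max_force_nn, self.pre_contact_span_nm
        )
        if not self.z_step_nm > 0:
            raise ValueError("z_step_nm must be > 0")
        if not self.max_force_nn > 0:
            raise ValueError("max_force_nn must be > 0")
        if self.force_noise_sd_nn is not None and self.force_noise_sd_nn < 0:
            raise ValueError("force_noise_sd_nn must be >= 0")

    @property
    def noise_sd(self) -> float:
        if self.force_noise_sd_nn is None:
            return 0.01 * self.max_force_nn
        return self.force_noise_sd_nn


@lru_cache(maxsize=256)
def _blend_scale(sample: TwoLayerSampleModel) -> float:
    """Logistic scale for the modulus blend.

    Starts at the width that saturates the blend to within ~1% of either
    end member at blend_start / blend_end.  For a softening profile
    (deep layer softer than the shell) a steep secant-modulus blend would
    make the force transiently decrease with depth, which is unphysical,
    so the scale is widened to the smallest value for which the forward
    force stays monotone non-decreasing.
    """
    span = sample.blend_end_nm - sample.blend_start_nm
    scale = 0.5 * span / _LOGISTIC_SATURATION
    drop = sample.e_shallow_kpa - sample.e_deep_kpa
    if drop <= 0:
        return scale
    mid = 0.5 * (sample.blend_start_nm + sample.blend_end_nm)
    delta = np.linspace(1.0, sample.blend_end_nm + 10 * max(scale, span), 2000)
    for _ in range(200):
        w = expit((delta - mid) / scale)
        e_app = sample.e_shallow_kpa - drop * w
        de = -drop * w * (1.0 - w) / scale
        # dF/d(delta) has the sign of E'(d)*d + 2*E(d)
        if np.all(de * delta + 2.0 * e_app >= 0):
            return scale
        scale *= 1.05
    return scale


def apparent_modulus(delta_nm, sample: TwoLayerSampleModel):
    """Depth-dependent apparent modulus (kPa): logistic blend from the
    shallow to the deep modulus across the blend zone."""
    delta = np.asarray(delta_nm, dtype=float)
    mid = 0.5 * (sample.blend_start_nm + sample.blend_end_nm)
    scale = _blend_scale(sample)
    w = expit((delta - mid) / scale)
    return sample.e_shallow_kpa + (sample.e_deep_kpa - sample.e_shallow_kpa) * w


def layered_cone_force(delta_nm, sample: TwoLayerSampleModel, probe: ProbeModel):
    """Forward model (nN): Sneddon cone force with the depth-dependent
    apparent modulus."""
    delta = np.asarray(delta_nm, dtype=float)
    pref = _cone_prefactor(probe.half_cone_angle_deg, sample.poisson)
    return pref * apparent_modulus(delta, sample) * delta**2


def _layered_force_gradient(delta_nm, sample: TwoLayerSampleModel, probe: ProbeModel):
    """dF/d(delta) (nN/nm) of the forward model, for Newton iterations."""
    delta = np.asarray(delta_nm, dtype=float)
    pref = _cone_prefactor(probe.half_cone_angle_deg, sample.poisson)
    mid = 0.5 * (sample.blend_start_nm + sample.blend_end_nm)
    scale = _blend_scale(sample)
    w = expit((delta - mid) / scale)
    e_app = sample.e_shallow_kpa + (sample.e_deep_kpa - sample.e_shallow_kpa) * w
    de_app = (sample.e_deep_kpa - sample.e_shallow_kpa) * w * (1.0 - w) / scale
    return pref * (de_app * delta**2 + 2.0 * e_app * delta)


def simulate_force_curve(
    sample: TwoLayerSampleModel,
    probe: Optional[ProbeModel] = None,
    acq: Optional[AcquisitionParams] = None,
) -> Tuple[ForceCurve, pd.DataFrame]:
    """Simulate one approach sweep over a two-layer sample.

    The sweep starts with ``pre_contact_span_nm`` of flat baseline; past
    the contact point the indentation at each piezo position solves
    depth + F(depth)/k = z - z0 (cantilever bending subtracts from piezo
    travel), so the rendered (z, deflection) pair is exactly consistent
    with the forward model.  Zero-mean Gaussian force noise of SD
    ``acq.noise_sd`` is added to the deflection channel, and the sweep
    stops once the noise-free force reaches ``max_force_nn``.
    """
    probe = probe or ProbeModel()
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(acq.seed)
    k = probe.spring_constant
    z0 = acq.pre_contact_span_nm

    delta_max = brentq(
        lambda d: layered_cone_force(d, sample, probe) - acq.max_force_nn, 0.0, 1e6
    )
    z_end = z0 + delta_max + acq.max_force_nn / k
    z = np.arange(0.0, z_end + 2 * acq.z_step_nm, acq.z_step_nm)

    deflection = np.zeros_like(z)
    contact = z > z0
    travel = z[contact] - z0
    # initialise depth from a dense forward grid, then polish by Newton
    grid = np.linspace(0.0, delta_max * 1.05, 4096)
    grid_z = grid + layered_cone_force(grid, sample, probe) / k
    depth = np.interp(travel, grid_z, grid)
    for _ in range(5):
        g = depth + layered_cone_force(depth, sample, probe) / k - travel
        gp = 1.0 + _layered_force_gradient(depth, sample, probe) / k
        depth = np.clip(depth - g / gp, 0.0, None)
    force_clean = layered_cone_force(depth, sample, probe)
    deflection[contact] = force_clean / k

    # stop at max force (noise-free criterion keeps the length deterministic)
    over = np.nonzero(force_clean >= acq.max_force_nn)[0]
    n_keep = z.size if over.size == 0 else int(np.nonzero(contact)[0][over[0]]) + 1
    z = z[:n_keep]
    deflection = deflection[:n_keep]

    deflection = deflection + rng.normal(0.0, acq.noise_sd / k, size=deflection.shape)

    curve = ForceCurve(
        z,
        deflection,
        spring_constant=k,
        meta={
            "max_force_nN": acq.max_force_nn,
            "seed": acq.seed,
            "approach_velocity_um_per_s": 1.0,
        },
    )
    truth = pd.DataFrame(
        [
            {
                "e_shallow_kpa": sample.e_shallow_kpa,
                "e_deep_kpa": sample.e_deep_kpa,
                "blend_start_nm": sample.blend_start_nm,
                "blend_end_nm": sample.blend_end_nm,
                "contact_point_z_nm": z0,
                "force_noise_sd_nn": acq.noise_sd,
                "seed": acq.seed,
            }
        ]
    )
    return curve, truth


def simulate_afm_cohort(
    sample: TwoLayerSampleModel,
    n: int,
    probe: Optional[ProbeModel] = None,
    acq: Optional[AcquisitionParams] = None,
    seed: int = 0,
) -> Tuple[List[ForceCurve], pd.DataFrame]:
    """Simulate ``n`` independent indentations of one sample model.  Each
    curve gets its own child seed derived from ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    acq = acq or AcquisitionParams()
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n, 1)) % (2**31)
    curves, truths = [], []
    for i in range(n):
        acq_i = AcquisitionParams(
            z_step_nm=acq.z_step_nm,
            max_force_nn=acq.max_force_nn,
            pre_contact_span_nm=acq.pre_contact_span_nm,
            force_noise_sd_nn=acq.force_noise_sd_nn,
            seed=int(child_seeds[i]),
        )
        curve, truth = simulate_force_curve(sample, probe, acq_i)
        truth.insert(0, "curve_id", f"curve_{i:03d}")
        curves.append(curve)
        truths.append(truth)
    truth_table = (
        pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    )
    return curves, truth_table


# ---------------------------------------------------------------------------
# image scenes


def region_mask(spec: dict, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask for a region spec: ``{"kind": "disk", "center": (r, c),
    "radius": px}`` or ``{"kind": "rect", "top", "left", "height",
    "width"}``.  Regions extending outside the image are rejected."""
    mask = np.zeros(shape, dtype=bool)
    kind = spec.get("kind")
    if kind == "disk":
        (r, c), radius = spec["center"], spec["radius"]
        if r - radius < 0 or c - radius < 0 or r + radius >= shape[0] or c + radius >= shape[1]:
            raise ValueError("mask outside image")
        rr, cc = draw_disk((r, c), radius, shape=shape)
        mask[rr, cc] = True
    elif kind == "rect":
        top, left = spec["top"], spec["left"]
        bottom, right = top + spec["height"], left + spec["width"]
        if top < 0 or left < 0 or bottom > shape[0] or right > shape[1]:
            raise ValueError("mask outside image")
        mask[top:bottom, left:right] = True
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    return mask


def _default_membranes() -> list:
    # vertical nurse-cell membranes well clear of the default cluster disk
    return [((10, 140), (245, 140), 5), ((10, 180), (245, 180), 5), ((10, 220), (245, 220), 5)]


@dataclass(frozen=True)
class ImageSceneParams:
    """Two-channel fixed-follicle scene.

    ``membrane_segments`` is a list of ((r0, c0), (r1, c1), width_px).
    Fold factors are multiplicative enrichments (>= 1) over the cytoplasm
    level; the phalloidin membrane fold is independent of the pMRLC folds.
    Noise is counting (Poisson) noise at ``photons_per_au`` detected
    photons per intensity unit; None renders a noiseless scene.
    """

    shape: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.2
    membrane_segments: list = field(default_factory=_default_membranes)
    membrane_fold_pmrlc: float = 2.5
    membrane_fold_phalloidin: float = 3.0
    cluster_mask_spec: dict = field(
        default_factory=lambda: {"kind": "disk", "center": (80, 64), "radius": 20}
    )
    cluster_boundary_fold_pmrlc: float = 2.0
    cytoplasm_level_per_channel: Dict[str, float] = field(
        default_factory=lambda: {"pmrlc": 100.0, "phalloidin": 120.0}
    )
    channel_gain: float = 1.0
    photons_per_au: Optional[float] = 4.0
    seed: int = 0

    def __post_init__(self):
        for fold in (
            self.membrane_fold_pmrlc,
            self.membrane_fold_phalloidin,
            self.cluster_boundary_fold_pmrlc,
        ):
            if not fold >= 1:
                raise ValueError("fold factors must be >= 1 (enrichment)")
        if any(v < 0 for v in self.cytoplasm_level_per_channel.values()):
            raise ValueError("intensities must be >= 0")
        if not self.channel_gain > 0:
            raise ValueError("channel_gain must be > 0")


def _membrane_mask(segments, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1), width in segments:
        for r, c in ((r0, c0), (r1, c1)):
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError("mask outside image")
        skeleton = np.zeros(shape, dtype=bool)
        rr, cc = draw_line(r0, c0, r1, c1)
        skeleton[rr, cc] = True
        if width > 1:
            skeleton = binary_dilation(skeleton, disk_footprint((width - 1) // 2))
        mask |= skeleton
    return mask


def simulate_follicle_image(params: ImageSceneParams) -> Tuple[FollicleImage, pd.DataFrame]:
    """Render a two-channel follicle scene and its expected-ratio truth.

    pMRLC = cytoplasm level x membrane fold (on membranes) x cluster fold
    (on the cluster mask) x gain; phalloidin carries only its own membrane
    enrichment.  Ground truth records the expected membrane peak ratio
    (pMRLC/phalloidin at a membrane) and the expected cluster/cytoplasm
    pMRLC ratio, computed from the noiseless scene, both gain-invariant.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    membranes = _membrane_mask(params.membrane_segments, shape)
    cluster = region_mask(params.cluster_mask_spec, shape)

    cyt = params.cytoplasm_level_per_channel
    pm_fold = np.ones(shape)
    pm_fold[membranes] = params.membrane_fold_pmrlc
    pm_fold[cluster] *= params.cluster_boundary_fold_pmrlc
    ph_fold = np.ones(shape)
    ph_fold[membranes] = params.membrane_fold_phalloidin

    clean = {
        "pmrlc": cyt["pmrlc"] * pm_fold * params.channel_gain,
        "phalloidin": cyt["phalloidin"] * ph_fold * params.channel_gain,
    }
    if params.photons_per_au is None:
        noisy = clean
    else:
        g = params.photons_per_au
        noisy = {name: rng.poisson(ch * g) / g for name, ch in clean.items()}

    image = FollicleImage(
        {name: ch.astype(float) for name, ch in noisy.items()},
        params.pixel_size_um,
        masks={"cluster": cluster, "membranes": membranes},
    )
    truth = pd.DataFrame(
        [
            {
                "membrane_ratio": float(
                    clean["pmrlc"][membranes].max() / clean["phalloidin"][membranes].max()
                ),
                "cluster_cytoplasm_ratio": float(
                    clean["pmrlc"][cluster].mean() / (cyt["pmrlc"] * params.channel_gain)
                ),
                "seed": params.seed,
            }
        ]
    )
    return image, truth


# ---------------------------------------------------------------------------
# time-lapse movies


@dataclass(frozen=True)
class TimelapseParams:
    """Transient-puncta movie.

    Puncta are born at a Poisson rate per frame, uniformly inside the
    cluster mask but no closer than ``min_separation_px`` to any punctum
    alive in the current or previous frame (so distinct puncta remain
    distinct to a gapless nearest-neighbour tracker).  Each punctum lives
    an integer number of consecutive frames drawn from a geometric
    distribution whose mean duration (frames x frame_interval) equals
    ``mean_lifetime_s``, and is rendered as a static Gaussian spot over a
    uniform background with counting noise.
    """

    n_frames: int = 120
    frame_interval_s: float = 30.0
    birth_rate_per_frame: float = 1.5
    mean_lifetime_s: float = 70.2
    punctum_intensity: float = 150.0
    punctum_sigma_px: float = 1.5
    cluster_mask_spec: dict = field(
        default_factory=lambda: {"kind": "disk", "center": (64, 64), "radius": 48}
    )
    shape: Tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.2
    background_level: float = 20.0
    photons_per_au: Optional[float] = 4.0
    min_separation_px: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        if not self.mean_lifetime_s >= self.frame_interval_s:
            raise ValueError("mean_lifetime_s must be >= frame_interval_s")
        if self.birth_rate_per_frame < 0:
            raise ValueError("birth_rate_per_frame must be >= 0")


def sample_lifetimes(
    n: int, mean_lifetime_s: float, frame_interval_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` per-punctum frame counts from the geometric distribution
    on {1, 2, ...} whose mean duration equals ``mean_lifetime_s``.  The
    first-present-to-first-absent lifetime convention (frames x interval)
    then recovers the generator mean without discretisation bias."""
    if not mean_lifetime_s >= frame_interval_s:
        raise ValueError("mean_lifetime_s must be >= frame_interval_s")
    p = frame_interval_s / mean_lifetime_s
    return rng.geometric(p, size=n)


def simulate_timelapse(params: TimelapseParams) -> Tuple[TimeLapse, pd.DataFrame]:
    """Render a puncta movie and its per-punctum ground truth (position,
    birth frame, frame count, censoring flag)."""
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    mask = region_mask(params.cluster_mask_spec, shape)
    margin = int(np.ceil(2 * params.punctum_sigma_px)) + 2
    interior = binary_erosion(mask, disk_footprint(margin))
    sites = np.argwhere(interior)
    if sites.size == 0:
        raise ValueError("cluster mask too small for the punctum footprint")

    records = []  # (row, col, birth, n_frames)
    for t in range(params.n_frames):
        for _ in range(rng.poisson(params.birth_rate_per_frame)):
            n_frames = int(sample_lifetimes(1, params.mean_lifetime_s, params.frame_interval_s, rng)[0])
            # positions of puncta alive in this or the previous frame
            occupied = np.array(
                [
                    (r, c)
                    for r, c, birth, k in records
                    if birth <= t <= birth + k - 1 or birth <= t - 1 <= birth + k - 1
                ]
            )
            placed = False
            for _attempt in range(20):
                r, c = sites[rng.integers(len(sites))]
                if occupied.size == 0 or np.all(
                    np.hypot(occupied[:, 0] - r, occupied[:, 1] - c) >= params.min_separation_px
                ):
                    placed = True
                    break
            if placed:
                records.append((int(r), int(c), t, n_frames))

    frames = np.full((params.n_frames,) + shape, params.background_level, dtype=float)
    half = int(np.ceil(4 * params.punctum_sigma_px))
    for r, c, birth, k in records:
        rr = np.arange(max(r - half, 0), min(r + half + 1, shape[0]))
        cc = np.arange(max(c - half, 0), min(c + half + 1, shape[1]))
        patch = params.punctum_intensity * np.exp(
            -((rr[:, None] - r) ** 2 + (cc[None, :] - c) ** 2)
            / (2 * params.punctum_sigma_px**2)
        )
        last = min(birth + k - 1, params.n_frames - 1)
        frames[birth : last + 1, rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1] += patch

    if params.photons_per_au is not None:
        g = params.photons_per_au
        frames = rng.poisson(frames * g) / g

    movie = TimeLapse(frames, params.frame_interval_s, params.pixel_size_um, mask)
    truth = pd.DataFrame(
        [
            {
                "punctum_id": i,
                "row": r,
                "col": c,
                "birth_frame": birth,
                "n_frames": k,
                "censored": birth + k - 1 >= params.n_frames - 1,
            }
            for i, (r, c, birth, k) in enumerate(records)
        ],
        columns=["punctum_id", "row", "col", "birth_frame", "n_frames", "censored"],
    )
    return movie, truth


# ---------------------------------------------------------------------------
# follicle geometry tables

DistributionSpec = Union[float, dict]


def _sample_dist(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a distribution spec: a bare number (degenerate), or
    ``{"dist": "normal", "mean", "sd"}`` / ``{"dist": "uniform", "low",
    "high"}``."""
    if isinstance(spec, (int, float)):
        return np.full(n, float(spec))
    if spec["dist"] == "normal":
        return rng.normal(spec["mean"], spec["sd"], size=n)
    if spec["dist"] == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=n)
    raise ValueError(f"unknown distribution {spec!r}")


def simulate_follicle_geometry(
    n: int,
    border_front_um: DistributionSpec = {"dist": "normal", "mean": 150.0, "sd": 20.0},
    follicle_front_um: DistributionSpec = {"dist": "normal", "mean": 150.0, "sd": 10.0},
    follicle_length_um: DistributionSpec = {"dist": "normal", "mean": 200.0, "sd": 15.0},
    cluster_length_um: Optional[DistributionSpec] = 20.0,
    seed: int = 0,
) -> List[FollicleGeometry]:
    """Sample ``n`` follicle geometry records.  Records violating the
    geometric invariants (non-positive distances, a front beyond the
    follicle length) are rejected and dropped."""
    rng = np.random.default_rng(seed)
    border = _sample_dist(border_front_um, n, rng)
    follicle = _sample_dist(follicle_front_um, n, rng)
    length = _sample_dist(follicle_length_um, n, rng)
    cl = (
        _sample_dist(cluster_length_um, n, rng)
        if cluster_length_um is not None
        else np.full(n, np.nan)
    )
    out = []
    for b, f, ln, c in zip(border, follicle, length, cl):
        if not (b > 0 and 0 < f <= ln and b <= ln):
            continue  # rejected record
        if np.isnan(c):
            out.append(FollicleGeometry(b, f, ln))
        else:
            rear = max(b - c, 0.0)
            out.append(FollicleGeometry(b, f, ln, cluster_front=b, cluster_rear=rear))
    return out
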