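"""AFM nanoindentation analysis for layered soft tissue.

Converts approach force curves (piezo extension vs cantilever deflection)
into force-indentation data and extracts Young's moduli by fitting the
Sneddon cone (Hertzian) contact model over stated indentation windows.
For a rigid conical indenter of half-opening angle ``alpha`` pressed a
depth ``delta`` into an incompressible elastic half-space,

    F = (2 / pi) * tan(alpha) * E / (1 - nu_s**2) * delta**2,

so a zero-intercept linear regression of ``F`` on ``delta**2`` over a
depth window gives the apparent Young's modulus ``E`` for the material
probed at those depths.  On a follicle, a shallow window (default
20-100 nm) reports on the basement-membrane shell while a deep window
(default 310-550 nm) reports on the underlying nurse cells.

Units throughout: lengths in nm, forces in nN, moduli in kPa, cantilever
spring constants in N/m (so force_nN = k_N_per_m * deflection_nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    EmptyCohortError,
    InsufficientIndentationError,
    NoBaselineError,
    NoContactError,
    NonPhysicalFitError,
    SparseWindowError,
)

#: Default indentation windows (nm): basement membrane and nurse cells.
SHALLOW_WINDOW = (20.0, 100.0)
DEEP_WINDOW = (310.0, 550.0)

#: Default Poisson ratios: incompressible tissue, silicon-nitride tip.
SAMPLE_POISSON = 0.5
TIP_POISSON = 0.25


@dataclass(frozen=True)
class ProbeModel:
    """Conical AFM probe.

    ``tip_modulus_kpa`` is the string ``"rigid"`` for the classic Sneddon
    solution, or a modulus in kPa to fit through the reduced modulus
    1/E* = (1 - nu_s^2)/E_s + (1 - nu_t^2)/E_t instead.
    """

    spring_constant: float = 0.12  # N/m
    half_cone_angle_deg: float = 20.0
    poisson_tip: float = TIP_POISSON
    tip_modulus_kpa: object = "rigid"

    def __post_init__(self):
        if not (np.isfinite(self.spring_constant) and self.spring_constant > 0):
            raise ValueError("spring_constant must be finite and > 0")
        if not 0 < self.half_cone_angle_deg < 90:
            raise ValueError("half_cone_angle_deg must lie in (0, 90)")
        if self.tip_modulus_kpa != "rigid":
            if not (np.isfinite(self.tip_modulus_kpa) and self.tip_modulus_kpa > 0):
                raise ValueError("tip_modulus_kpa must be 'rigid' or a positive modulus")


@dataclass
class ForceCurve:
    """One approach sweep: piezo extension ``z`` (nm, increasing toward the
    sample) and cantilever deflection (nm), with the calibrated spring
    constant (N/m) and free-form acquisition metadata."""

    z: np.ndarray
    deflection: np.ndarray
    spring_constant: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.shape != self.deflection.shape or self.z.ndim != 1:
            raise ValueError("z and deflection must be 1-D arrays of equal length")
        if self.z.size < 50:
            raise ValueError("force curve must contain at least 50 samples")
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be > 0")


@dataclass
class ForceIndentation:
    """Baseline-subtracted force (nN) against indentation depth (nm),
    sorted by depth, with the contact point used for the conversion."""

    delta: np.ndarray
    force: np.ndarray
    contact_point_z: float


@dataclass
class HertzFitResult:
    modulus_kpa: float
    window: tuple
    n_points: int
    rss: float
    r_squared: float
    tip_model: str = "rigid"


@dataclass
class TwoWindowResult:
    """Partial-result container for one curve: each window holds either a
    fit or an error message (never both)."""

    curve_id: str
    contact_point_z: float
    shallow: Optional[HertzFitResult]
    deep: Optional[HertzFitResult]
    errors: dict = field(default_factory=dict)


@dataclass
class CohortStiffness:
    label: str
    moduli_kpa: np.ndarray
    mean_kpa: float
    sd_kpa: float
    n: int


# force prefactor: F_nN = _prefactor * E_kPa * delta_nm^2
# (kPa * nm^2 = 1e3 Pa * 1e-18 m^2 = 1e-15 N = 1e-6 nN)
def _cone_prefactor(half_cone_angle_deg: float, poisson_sample: float) -> float:
    return (2.0 / math.pi) * math.tan(math.radians(half_cone_angle_deg)) / (
        1.0 - poisson_sample**2
    ) * 1e-6


def cone_force(delta_nm, modulus_kpa, half_cone_angle_deg=20.0, poisson_sample=SAMPLE_POISSON):
    """Sneddon cone force (nN) at indentation ``delta_nm`` for modulus
    ``modulus_kpa``.  Accepts arrays; ``modulus_kpa`` may be depth-dependent."""
    delta = np.asarray(delta_nm, dtype=float)
    return _cone_prefactor(half_cone_angle_deg, poisson_sample) * modulus_kpa * delta**2


def pointwise_modulus(force_nn, delta_nm, half_cone_angle_deg=20.0, poisson_sample=SAMPLE_POISSON):
    """Closed-form per-point modulus E = F * pi * (1 - nu^2) / (2 tan(a) d^2),
    in kPa.  The independent oracle for the windowed regression."""
    delta = np.asarray(delta_nm, dtype=float)
    return np.asarray(force_nn, dtype=float) / (
        _cone_prefactor(half_cone_angle_deg, poisson_sample) * delta**2
    )


def _first_persistent_run(mask: np.ndarray, run: int) -> Optional[int]:
    """Index of the first sample of the first run of >= ``run`` consecutive
    True values, or None."""
    if mask.size < run:
        return None
    window = np.convolve(mask.astype(int), np.ones(run, dtype=int), mode="valid")
    hits = np.nonzero(window == run)[0]
    return int(hits[0]) if hits.size else None


def estimate_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    k_sd: float = 3.0,
    force_band: tuple = (0.15, 0.85),
) -> float:
    """Estimate the contact point z0 (nm) of an approach sweep.

    Baseline statistics come from the leading ``baseline_fraction`` of the
    sweep.  A rough onset is the first sample whose deflection exceeds the
    baseline mean + ``k_sd`` * baseline SD and stays above for at least 5
    consecutive samples.  That crossing is systematically late in noisy
    data — under a stiff superficial shell the force within the first tens
    of nanometres of contact sits below the noise floor — so z0 is refined
    where the signal is strong: over the samples whose force lies in
    ``force_band`` (fractions of the final recorded force), the cone model
    gives sqrt(F) proportional to tip-sample displacement, so a linear fit
    of sqrt(F) against (z - deflection) is extrapolated to zero force and
    its x-intercept is z0.  If the refinement is ill-posed (too few points
    in the band, non-positive slope, or an intercept far from the
    threshold crossing) the crossing itself is returned.
    """
    z = curve.z
    n_base = int(len(z) * baseline_fraction)
    if n_base < 5:
        raise NoBaselineError("baseline region shorter than 5 samples")
    baseline = curve.deflection[:n_base]
    d = curve.deflection - baseline.mean()
    threshold = k_sd * baseline.std()

    onset = _first_persistent_run(d > threshold, 5)
    if onset is None:
        raise NoContactError("no contact detected")
    if onset < 5:
        raise NoBaselineError("no baseline: sweep appears to start in contact")
    z_cross = float(z[onset])
    z_step = float(np.median(np.diff(z)))

    force = curve.spring_constant * d  # nN
    f_end = float(force[-5:].mean())
    # band edges from a smoothed trace so membership does not correlate
    # with any sample's own noise (which would bias the intercept)
    w = min(9, 2 * (z.size // 2) - 1)
    smooth = np.convolve(force, np.full(w, 1.0 / w), mode="same")
    lo, hi = force_band[0] * f_end, force_band[1] * f_end
    past_lo = np.nonzero((np.arange(z.size) >= onset) & (smooth >= lo))[0]
    past_hi = np.nonzero(smooth >= hi)[0]
    if f_end > 0 and past_lo.size:
        i_lo = past_lo[0]
        i_hi = past_hi[0] if past_hi.size else z.size - 1
        if i_hi - i_lo >= 10:
            sel = slice(i_lo, i_hi + 1)
            x = z[sel] - d[sel]
            y = np.sqrt(np.clip(force[sel], 0.0, None))
            slope, intercept = np.polyfit(x, y, 1)
            if slope > 0:
                z0 = -intercept / slope
                if z[0] <= z0 <= z_cross + 5 * z_step:
                    return float(z0)
    return z_cross


def to_force_indentation(
    curve: ForceCurve, z0: float, baseline_fraction: float = 0.3
) -> ForceIndentation:
    """Convert a sweep to baseline-subtracted force vs indentation.

    F = k * (deflection - baseline mean); depth = (z - z0) - (deflection -
    baseline mean), i.e. piezo travel past contact minus cantilever bending.
    Only points with non-negative depth are kept, sorted by depth.
    """
    if not (curve.z[0] <= z0 <= curve.z[-1]):
        raise ValueError("contact point outside the sweep range")
    n_base = int(len(curve.z) * baseline_fraction)
    d = curve.deflection - curve.deflection[:n_base].mean()
    force = curve.spring_constant * d
    depth = (curve.z - z0) - d
    keep = depth >= 0
    if keep.sum() < 10:
        raise InsufficientIndentationError("insufficient indentation")
    order = np.argsort(depth[keep], kind="stable")
    return ForceIndentation(depth[keep][order], force[keep][order], float(z0))


def fit_hertz_cone(
    fi: ForceIndentation,
    window: tuple,
    sample_poisson: float = SAMPLE_POISSON,
    probe: Optional[ProbeModel] = None,
) -> HertzFitResult:
    """Windowed Sneddon-cone fit: zero-intercept least squares of F on
    delta^2 over points with window[0] <= delta <= window[1].

    With a rigid tip, E = slope * pi * (1 - nu_s^2) / (2 tan alpha).  With a
    finite ``probe.tip_modulus_kpa``, the slope yields the reduced modulus
    E* and the sample modulus is solved from
    1/E* = (1 - nu_s^2)/E_s + (1 - nu_t^2)/E_t.
    """
    probe = probe or ProbeModel()
    lo, hi = window
    if not lo < hi:
        raise ValueError("window lower bound must be below upper bound")
    sel = (fi.delta >= lo) & (fi.delta <= hi)
    n_points = int(sel.sum())
    if n_points < 5:
        raise SparseWindowError(f"window too sparse: {n_points} points in {window}")
    d2 = fi.delta[sel] ** 2
    f = fi.force[sel]
    slope = float(np.dot(f, d2) / np.dot(d2, d2))  # nN / nm^2
    if slope <= 0:
        raise NonPhysicalFitError("non-physical fit: non-positive slope")

    tan_a = math.tan(math.radians(probe.half_cone_angle_deg))
    if probe.tip_modulus_kpa == "rigid":
        modulus = slope * 1e6 * math.pi * (1.0 - sample_poisson**2) / (2.0 * tan_a)
        tip_model = "rigid"
    else:
        e_star = slope * 1e6 * math.pi / (2.0 * tan_a)  # kPa
        inv_sample = 1.0 / e_star - (1.0 - probe.poisson_tip**2) / probe.tip_modulus_kpa
        if inv_sample <= 0:
            raise NonPhysicalFitError("non-physical fit: tip compliance exceeds total")
        modulus = (1.0 - sample_poisson**2) / inv_sample
        tip_model = f"finite:{probe.tip_modulus_kpa:g}kPa"

    resid = f - slope * d2
    rss = float(np.dot(resid, resid))
    tss = float(np.sum((f - f.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else 1.0
    return HertzFitResult(modulus, (float(lo), float(hi)), n_points, rss, r_squared, tip_model)


def analyze_curve_two_windows(
    curve: ForceCurve,
    shallow_window: tuple = SHALLOW_WINDOW,
    deep_window: tuple = DEEP_WINDOW,
    sample_poisson: float = SAMPLE_POISSON,
    probe: Optional[ProbeModel] = None,
    curve_id: str = "",
    **contact_kwargs,
) -> TwoWindowResult:
    """Full per-curve chain: contact point, conversion, and both windowed
    fits.  A window that cannot be fitted (e.g. the sweep stopped before
    reaching it) is reported in ``errors`` while the other fit is still
    returned; contact/conversion failures abort the curve and re-raise with
    the curve identifier attached."""
    probe = probe or ProbeModel()
    try:
        z0 = estimate_contact_point(curve, **contact_kwargs)
        fi = to_force_indentation(curve, z0)
    except (NoContactError, NoBaselineError, InsufficientIndentationError) as exc:
        raise type(exc)(f"curve {curve_id or '<unnamed>'}: {exc}") from exc

    result = TwoWindowResult(curve_id, z0, None, None)
    for name, window in (("shallow", shallow_window), ("deep", deep_window)):
        try:
            setattr(result, name, fit_hertz_cone(fi, window, sample_poisson, probe))
        except (SparseWindowError, NonPhysicalFitError) as exc:
            result.errors[name] = str(exc)
    return result


def aggregate_cohort(fits: Sequence[HertzFitResult], label: str) -> CohortStiffness:
    """Pool per-indentation moduli into a cohort summary (mean, sample SD,
    n).  Each fit is one indentation; repeats at a position each count."""
    if len(fits) == 0:
        raise EmptyCohortError("empty cohort")
    moduli = np.array([f.modulus_kpa for f in fits], dtype=float)
    sd = float(moduli.std(ddof=1)) if moduli.size > 1 else 0.0
    return CohortStiffness(label, moduli, float(moduli.mean()), sd, int(moduli.size))
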