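# Methods

This note records the models implemented by `folliquant`, the defaults
that matter, what the synthetic-data generators do and do not emulate,
and the numerical choices a maintainer would want to know about.

## AFM stiffness extraction

### Contact model

A conical indenter of half-opening angle α pressed a depth δ into an
elastic half-space obeys the Sneddon (Hertzian) relation

    F = (2/π) · tan α · E / (1 − ν_s²) · δ²,

with E the Young's modulus and ν_s the sample Poisson ratio.  The
package works in nm / nN / kPa / (N/m), where the relation becomes
F[nN] = (2/π) tan α · E[kPa] / (1 − ν_s²) · δ[nm]² · 10⁻⁶.  Defaults
follow the acquisition described for the follicle measurements: spring
constant k = 0.12 N/m, α = 20°, ν_s = 0.5 (incompressible tissue),
ν_t = 0.25.  The tip is treated as rigid by default; a finite tip
modulus can be supplied, in which case the fit slope yields the reduced
modulus 1/E* = (1 − ν_s²)/E_s + (1 − ν_t²)/E_t and E_s is solved from
it.  At a 150 GPa silicon-nitride modulus against ~10 kPa tissue the two
treatments differ by well under 0.1%, which is why "rigid" is the
default; the choice is recorded in each fit result.

### Windowed fits

A Stage 9 follicle is a layered sample: a basement-membrane shell over
much softer nurse cells.  Following the study's procedure, each
force-indentation curve is fitted twice over fixed depth windows —
20–100 nm (basement membrane) and 310–550 nm (nurse cells).  Each fit is
a zero-intercept least squares of F on δ² over the in-window points.
This is exact for the model, deterministic, and needs no initial guess;
nonlinear optimisation would add nothing.  A window containing fewer
than 5 points is reported as too sparse (a sweep truncated at its force
ceiling before 310 nm still yields the shallow fit); a non-positive
slope is a non-physical fit.  "Tip depth" windows are interpreted as
sample indentation δ, not raw piezo travel.

### Conversion and contact point

Force is k × baseline-subtracted deflection; indentation is piezo travel
past contact minus cantilever bending, δ = (z − z₀) − d.  Baseline
statistics use the leading 30% of the sweep (the simulated pre-contact
span is sized so that region is genuinely off-sample).

The contact point z₀ is the step that deserves the most care.  A
threshold rule (deflection above baseline mean + 3 SD for ≥ 5
consecutive samples) detects *that* contact happened, but under a stiff
shell it fires long after the true contact: with ~0.25 nm deflection
noise, the force generated in the first ~100 nm of indentation into a
~24 kPa shell is below the noise floor, and the shallow-window modulus
is extremely sensitive to z₀ error (roughly 2% per nm).  z₀ is therefore
refined where the signal is strong: over the samples whose force lies
between 15% and 85% of the final recorded force, the cone model makes
√F linear in tip-sample displacement (z − d), so an ordinary
least-squares line through (z − d, √F) extrapolated to zero force has
x-intercept z₀.  Two details matter:

* band membership is decided on a smoothed force trace (9-sample moving
  average), never point-by-point on raw values — otherwise points enter
  the band *because* their noise fluctuated upward, and that same noise
  in √F tilts the line and biases the intercept early by tens of nm;
* the lower band edge is kept above the layer-transition regime, where
  the apparent modulus still varies with depth and √F is not yet linear.

If the refinement is ill-posed (too few band points, non-positive slope,
intercept far beyond the threshold crossing) the threshold crossing is
used as-is.  The estimator is translation-equivariant and, on noiseless
curves, exact to a fraction of a z-step.

### Cohorts

Each recorded indentation contributes one modulus per window; repeats at
a position are separate indentations (as in the study's per-indentation
scatter plots).  Cohorts report mean, sample SD and n.

## Fixed-image quantification

* **Membrane ratio** — both channels are sampled along a
  membrane-crossing line at ~1 px spacing with bilinear interpolation
  and smoothed with a 3-sample moving average (a stand-in for the
  implicit visual smoothing of manual peak reading; configurable).  The
  pMRLC peak is the smoothed argmax; phalloidin is read at the same
  sample index — the literal "at the same point" reading.  The
  alternative (phalloidin's own local peak) is not used.  Three lines
  are averaged per follicle, and follicle scores are divided by the mean
  of the control group *of the same experimental batch*, so the control
  normalises to exactly 1 batch-wise.
* **Cluster ratio** — mean pMRLC over the traced cluster mask divided by
  the mean over the identical mask translated into nurse-cell cytoplasm.
  The translation is a configured vector (reproducible, unlike manual
  placement) and is rejected if it leaves the image or lands on a
  membrane mask.
* **Puncta** — background is the median over the cluster mask with a
  1.4826·MAD robust SD; punctum pixels exceed background + 3 robust SD,
  8-connected components of ≥ 4 px whose peak also clears background +
  5 robust SD count as puncta.  The peak-prominence rule exists because
  pure counting noise occasionally clears an area-only rule.  Punctum
  length is the Feret diameter (maximum pairwise pixel-centre distance)
  times the pixel size.  Detection parameters are logged with each run;
  they replace the study's manual counting, whose criteria are unstated.
* **Migration index** — border-cell distance over outer-follicle-cell
  distance, both from the anterior pole; ≈1 on-time, <1 delayed,
  >1 accelerated (classification tolerance ±0.05, configurable).
  Cluster length is front minus rear.  Both are scale-invariant.

## Puncta dynamics

Per-frame detection uses the same detector as fixed images.  Linking is
greedy nearest-neighbour between consecutive frames within 4 px, ties
broken by smallest distance then canonical (centroid-sorted) detection
order, which makes the track set independent of detection ordering.
There is no gap closing by default (`max_gap = 0`): a lifetime ends when
the punctum has disappeared completely, so a one-frame disappearance
terminates the track.  Greedy assignment rather than global (Hungarian)
assignment is adequate at the sparse puncta densities of these movies
and is deterministic.

Lifetime = frames present × frame interval (equivalently first-absent −
first-present), so a single-frame punctum at a 30 s interval has a 30 s
lifetime rather than 0.  Tracks present in the final frame
(right-censored) or the first frame (left-censored) are excluded from
the mean and their counts reported; excluding them is unbiased because
exclusion depends on birth time, not duration.

## Synthetic data: what it emulates, what it does not

The study's raw curves and stacks are not deposited, so every stage is
validated by parameter recovery on generated data.

* **Force curves** — a two-layer sample is modelled by a depth-dependent
  apparent modulus: a logistic blend from E_shallow to E_deep between
  blend_start (150 nm) and blend_end (300 nm), inserted into the cone
  relation as a secant modulus.  This is a deliberate surrogate for full
  layered elasticity, chosen because the analysis itself treats the two
  windows as independent Hertz fits; the blend is calibrated so that the
  apparent modulus sits within ~1% of either end member across the fit
  windows.  For softening profiles a steep secant blend would make force
  transiently decrease with depth, which is unphysical, so the logistic
  scale widens automatically to the smallest monotone-preserving width.
  At each piezo position the indentation solves δ + F(δ)/k = z − z₀
  (dense forward grid + Newton polish), so rendered sweeps are exactly
  consistent with the forward model; Gaussian force noise (default 1% of
  the 3 nN force ceiling — the instrument's noise is not published) is
  added to the deflection channel and the sweep stops at the ceiling.
  Not modelled: adhesion, viscoelasticity, tilt/virtual deflection,
  piezo creep.  Passing recovery tests therefore shows the windowed-fit
  chain is correct and unbiased under the stated noise, not that it is
  robust to un-modelled instrument artefacts.
* **Follicle scenes** — uniform cytoplasm, straight membrane segments
  with multiplicative enrichment folds per channel, a cluster region
  with its own pMRLC fold, Poisson counting noise at 4 detected photons
  per intensity unit (~5% relative noise at the cytoplasm level, typical
  of confocal acquisitions).  Ground-truth ratios are computed from the
  noiseless scene and are gain-invariant by construction.  Real
  follicles have curved, heterogeneous membranes and out-of-focus light;
  the scenes validate the measurement arithmetic, not segmentation.
* **Movies** — puncta are born at a Poisson rate per frame, uniformly
  inside the cluster mask but at least 12 px from any punctum alive in
  the current or previous frame, live an integer number of frames drawn
  from the geometric distribution on {1, 2, …} whose mean duration
  equals the target lifetime, and render as static Gaussian spots over a
  uniform background with counting noise.  The frame-grid lifetime law
  means the tracker's first-present→first-absent convention recovers the
  generator mean with no discretisation bias; the nucleation separation
  keeps distinct puncta resolvable to a gapless nearest-neighbour
  tracker (real puncta that nucleate on top of each other would be
  merged by manual scoring too).  Not modelled: punctum motion,
  photobleaching, focus drift.
* **Geometry tables** — distances drawn from configurable distributions,
  with records violating the geometric invariants rejected.

## Statistics

Two-group comparisons default to the Welch (unequal-variance) t-test —
the figure legends say only "unpaired t-test", group spreads visibly
differ, and the study's densitometry explicitly used the unequal-variance
form — with the Student form available and the choice recorded in the
output.  Three or more groups use one-way ANOVA with Tukey's HSD
(studentized range) adjusted pairwise p-values.  Tukey dominance over
unadjusted pairwise tests is guaranteed against the pooled-error (LSD)
unadjusted p, which is the comparison the test suite makes.  Stars
follow the figure convention (* <0.05 through **** <0.0001).

## Problem sizes used in validation

Stiffness recovery runs 50-curve cohorts per genotype (the published
per-genotype indentation counts are in the tens), at 2 nm z-steps and a
3 nN ceiling.  Lifetime recovery pools four 200-frame movies per group —
four follicles per genotype, as in the study — yielding on the order of
a thousand uncensored puncta, so the Monte-Carlo error of the pooled
mean sits near 2–4%.  All generators take explicit seeds and are
bit-for-bit reproducible.

## Known limitations

* The contact-point estimator assumes the quadratic (settled-layer)
  regime dominates its force band; exotic layer geometries that are
  still transitioning at mid-force would bias it.
* The secant-modulus surrogate is not a solution of layered elasticity;
  absolute window moduli on real layered tissue carry the usual
  thin-layer caveats.
* The tracker has no gap closing, by definition of the lifetime; blinking
  fluorophores would fragment tracks.
* Fixed-image puncta detection replaces manual counting; its parameters
  (3 SD threshold, 4 px minimum area, 5 SD peak) are logged but were not
  calibrated against human annotators.
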