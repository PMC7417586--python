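# Methods

This note documents the models, the numerical choices and the design
decisions behind `magrheo`, and what the synthetic-data tests do and do
not demonstrate about real measurements.

## Force calibration

The instrument's force on a superparamagnetic bead is modelled as
`F(I, d) = F0 · d^c(I)` with `c(I) = c1/(1 + c2·exp(c3·I))`, where `I` is
the coil current (A) and `d` the bead–needle distance (µm). `F0` is
expressed in nN for `d` in µm; because the exponent is current-dependent,
the formal unit of `F0` is `nN·µm^(−c)`, and every persisted model carries
this convention as an explicit string. The law is an empirical fit, valid
only inside the calibrated current and distance ranges; evaluation outside
them is flagged as extrapolation, and currents above the core's saturation
(default 1 A) are clamped with a warning, since above saturation the field
no longer grows with current. Zero current means the field is off and the
force is exactly zero — the fitted law must not be evaluated there (its
`I → 0` limit is a large nonzero force, an artifact of the functional
form).

Calibration proceeds in two stages from drag measurements in PDMS of known
kinematic viscosity (3000 or 5000 cSt, converted to dynamic viscosity with
a configurable density, default 0.97 g/cm³):

1. per current, the drift-corrected bead velocity at each distance gives
   the force via Stokes drag `F = 6πηRv`; `F = F0_I · d^(c_I)` is fitted
   by linear regression in log–log space (robust, and the residuals are
   multiplicative, matching the error structure of velocity ratios);
2. the per-current exponents are fitted with `c(I)` by nonlinear least
   squares with multi-start initialization over sign combinations of
   (c2, c3), keeping the best sum of squares; a constant exponent is
   returned as the boundary solution (c1 = c, c2 = 0) with a flag.

Drift correction: the scalar record is the Euclidean bead–needle distance;
its least-squares slope within each current-on interval is the raw speed,
and the mean slope of the flanking current-off windows (sedimentation
drift) is subtracted. A missing preceding off-phase (first pulse) falls
back to the following one, flagged. Optional moving-average pre-smoothing
(default 5 samples) uses odd-reflection padding so linear trends are
preserved at the record edges. Velocity is paired with the distance at the
interval midpoint; drag simulations for recovery tests therefore use short
(50 ms) pulses so the within-pulse distance change stays small and this
pairing is unbiased.

Force feedback inverts the law analytically:
`I(F, d) = (1/c3)·ln[((c1·ln d / ln(F/F0)) − 1)/c2]`. This is the exact
algebraic inverse of the two calibration equations (round trip verified to
1e−9 relative); a requested force whose needed exponent lies outside the
image of `c(I)`, or whose current falls outside the calibrated/saturation
range, raises an explicit out-of-range error, and the offline feedback
replay records such frames while clamping at saturation where possible.

## Creep rheology

Stress and strain are defined on the bead geometry: contact area
approximated by the bead cross-section `A = πr²` (a stated approximation —
the true bead–cell contact is smaller and geometry-dependent, so absolute
stiffness carries a systematic scale factor), `σ = ΔF/(πr²)`,
`ε = d(t)/r`, hence `J(t) = d(t)·πr/ΔF`. In practical units,
`J [1/Pa] = 1e−3·π·r[µm]·d[µm]/ΔF[nN]`.

Model fits are performed on `J(t)` in **linear** space (nonlinear least
squares), not log–log: the reported R² then refers to the creep curve
itself. The power law `J = J0·(t/t0)^β` uses t0 = 1 s, so `1/J0` is the
stiffness at the reference time; the sample at t = 0 is excluded (the
parameterization has singular support there), initialization comes from a
log–log regression, and β is bounded to [0, 2] with a flag above the
physical range [0, 1]. The Kelvin–Voigt fit flags τ as poorly constrained
when its standard error rivals it or when all samples lie on the plateau
(t_min > 3τ).

Multi-event protocols use Boltzmann superposition: for a linear
viscoelastic material, `d(t) = (1/(πr))·Σ_k ΔF_k·J(t − t_k)` over all
force-change events (force-off is an event with negative ΔF and the same
compliance — full-reversal assumption). The implementation is verified
against brute-force convolution of the protocol's force derivative with
J(t) on a 0.5 ms grid (agreement < 0.1%).

**Pulse trains and staircases.** Per-cycle (per-step) parameters are
obtained in the default "history-corrected" mode by a *joint* nonlinear
least-squares fit: one (J0, β) per cycle, with the model being the full
superposition of every cycle's creep and recovery, fitted simultaneously
over all on-phase windows. An earlier sequential formulation — fit cycle
1, subtract its modelled tail, fit cycle 2, and so on — is numerically
unstable under realistic position noise: each cycle's fit error perturbs
the background of all later cycles and the errors can cascade into
divergence by cycle 10. The joint fit solves the identical model without
the cascade and reduces to the same exact answer on noiseless data. The
alternative `history_corrected=False` mode simply re-zeroes the
displacement at each onset and fits cycles independently (it is biased
high after cycle 1 because it ignores the ongoing recovery of earlier
pulses, but matches what a per-pulse analysis without superposition would
report). Staircase steps are analyzed on the incremental stress (the step
increment ΔF); an absolute-stress mode is available as a switch.

**Recovery.** The relaxation after force-off is fitted as the
superposition of the frozen creep process and a new power-law recovery
process: `d(t > t_off) = (1/(πr))·[ΔF·J_creep(t − t_on) −
ΔF·J_rec(t − t_off)]`, with free (J0_rec, β_rec). Equal creep and recovery
compliances mean full (linear) recovery; a smaller recovery compliance
(higher recovery stiffness) quantifies unrecovered, plastic deformation.
Records whose post-off displacement does not decrease are flagged
"no recovery" but still fitted.

## Bead tracking

The tracking chain mirrors the live measurement software. Otsu's method
supplies the automatic threshold (dark foreground by default, with a
polarity flag; the threshold value itself is assigned to the dark class so
two-valued images binarize correctly; constant frames yield an empty mask
with a warning). Blob detection labels connected components and keeps
those whose equivalent diameter is within ±30% of the expected bead
diameter; the largest border-touching component is taken to be the needle
(it always enters from outside the field). A bead overlapping the needle
merges into that component and cannot be tracked; such "fused" beads are
reported heuristically as bead-radius-scale local maxima of the needle
component's distance transform.

Template tracking uses normalized cross-correlation of a static template
cut from the first frame (no re-templating: records are tens of seconds,
and template drift would accumulate), searched in a ±12 px window around
the previous position, with sub-pixel refinement by parabolic
interpolation of the 3×3 correlation neighbourhood; the track terminates
when the peak correlation falls below 0.5 (both window size and threshold
are implementation defaults, exposed as parameters). The correlation
localizes the template grid rather than the bead, so all positions are
shifted by the sub-pixel offset of the bead's dark-mass centroid within
the template itself; on noiseless rendered stacks the absolute RMS error
is ~0.02 px. Coordinates: 0-based pixel indices, positions at pixel
centres, x right / y down, physical conversion by the pixel size.

The needle contour is extracted at sub-pixel precision (marching squares
at level 0.5) from the needle component, and the bead–needle distance is
the minimum Euclidean distance from the bead centre to the contour — the
control variable of the force feedback, which the offline replay feeds
through the calibration inverse frame by frame.

## Virtual instrument

The simulator produces every input of the pipeline with known ground
truth.

* **Drag trajectories** integrate `dx/dt = −F(I, x)/(6πηR) + v_drift`
  with an explicit midpoint scheme at 50× the frame rate (the force varies
  strongly with distance), sampled down to the frame rate; reaching the
  needle truncates the record with a flag. Drift is constant and acts in
  all phases, as fluid settling does.
* **Creep displacements** evaluate the superposition sum exactly, with an
  optional per-event material assignment used to program stiffening
  scenarios (e.g. +5% stiffness per cycle, or `J0⁻¹ ∝ √F` stress
  stiffening) that the fitting stage must then recover.
* **Rendered images** show an anti-aliased dark bead disk and a dark
  needle silhouette on a bright background (16-bit, background 3000,
  contrast 2000 counts by default). The needle is a wedge with the default
  35° opening angle and a 10 µm tip-curvature radius, modelled as the
  union of the tangent disk and the cone truncated at the tangency line —
  note that with these parameters the conical flanks only begin ~7 µm
  behind the physical tip. The geometry object provides the exact
  surface-distance oracle used to validate the contour-based distance.
  An empty trajectory renders a single needle-only reference frame.
* **Noise models** are implementation defaults, not measured instrument
  properties (none are documented for the real setup): additive Gaussian
  position noise for trajectories; Gaussian read noise and optional
  Poisson shot noise for images, with SNR defined as contrast over read
  noise sd.
* **Populations** draw log-normal stiffness and normal fluidity; the
  defaults (ln GM = ln 277 Pa, sd(ln) = 1.28; fluidity 0.46 ± 0.25) are
  back-computed from a measured breast-carcinoma population's
  geometric-mean stiffness 277 ± 28 Pa and fluidity 0.46 ± 0.02 at
  n = 160 (error of the mean × √n gives the spread). Fluidity draws are
  clipped to the physical [0, 1] with the clip counts reported.
* **Fiber volumes** are random straight tubes (radius 2.5 voxels) stamped
  into the volume, blurred with a 0.6-voxel Gaussian PSF and given
  Poisson counting noise on a 150/10 peak/background — emulating
  *deconvolved* confocal stacks of collagen at the rescaled sampling.
  Real collagen differs in ways the generator does not capture (curved,
  bundled, wavy fibers; depth-dependent attenuation; anisotropic PSF), so
  passing tests demonstrate the correctness of the analysis chain, not
  segmentation performance on real gels. The spherical-cavity fixture
  provides exact pore ground truth.

Simulated drag calibrations use parameters (F0 = 700, c1 = −4, c2 = 1,
c3 = 1) for which the force *grows* with current (c2·c3 > 0), as in the
physical instrument, and stays at nN scale over the simulated distances.

## Population statistics

Stiffness is summarized by the geometric mean (log-normal data); its
error of the mean is reported both as the asymmetric factor interval
`exp(mean ± SEM of logs)` and as the symmetrized `GM·SEM(ln)`
approximation for "± Pa" display (the symmetric form is what measurement
tables conventionally print, but it is undefined in the literature, hence
both). Fluidity uses the arithmetic mean ± SEM. Group comparisons use
Welch's unequal-variance t-test — on log-transformed values for stiffness,
raw values for fluidity — with an *explicit* Bonferroni family size m
(`p_bonf = min(1, m·p)`); no implicit family inference is attempted.
Stars: * p < 0.05, ** p < 0.01, *** p < 0.001, assigned from the corrected
p. Two zero-variance groups compare to p = 1 (equal means) or 0. Optional
distribution diagnostics are available but are not gates. Fold changes are
last/first ratios with first-order error propagation.

## Pore analysis

Volumes carry per-axis voxel sizes (z, y, x) that propagate through every
distance computation. Lateral rescaling (e.g. to 37.5% for computational
efficiency, giving 0.13 µm/px from a 100 µm / 2048 px acquisition) updates
the voxel size so the physical extent is exactly preserved; binary volumes
are resampled nearest-neighbour to stay binary. The printed-resolution
convention is treated as µm per pixel throughout (0.13 µm/px laterally,
0.25 µm/px axially for 400 stacks over 100 µm).

Segmentation of the fibril phase: Gaussian pre-smoothing (σ = 1 voxel) +
global Otsu, with an optional per-plane local-adaptive mode. Because Otsu
always splits even a structureless histogram, a separability guard (the
foreground–background mean gap must exceed the larger of 3× the background
spread and 2× the global spread) returns an empty fibril mask for
noise-only volumes. Deconvolution is not implemented; the pipeline accepts
pre-deconvolved input.

Pore detection packs maximal inscribed spheres greedily on the
anisotropy-aware Euclidean distance transform of the fluid phase: accept
the largest-distance voxel as a centre with its distance as radius,
suppress all voxels the sphere covers (which also removes any candidate
centre inside an accepted sphere), repeat until the maximum falls below
the minimum radius (default 2 voxels — sub-resolution pores are noise).
Radii come from the one original transform and are only ever zeroed, so a
single descending sort enumerates candidates exactly. By construction
every sphere is fibril-free, radii scale exactly with voxel size, and
adding fibrils can never grow a pore. Summaries report both diameters and
medians (plot conventions differ on radius vs diameter).

## Pipeline and reproducibility

Each CLI subcommand validates its JSON/YAML config with pydantic before
any computation, writes the resolved config (with SHA-256 hash and package
version) next to its outputs, never mutates inputs, fixes CSV numeric
precision at 9 significant digits, and derives all per-stage randomness
deterministically from the single config seed — reruns are byte-identical.
Per-file analysis failures are recorded in the output table and the run
continues.

## Problem sizes used in validation

The validation suite runs entirely on simulated data at desk scale:
calibration grids of 6 currents × 6 distances; creep records of 80–400
frames at 40 Hz; 200 noise replicates for parameter-recovery statistics;
20 replicates for the pulse-train trend test (within one noisy record the
per-cycle estimates drift smoothly because the joint fit's errors are
correlated, so the no-trend check uses the mean per-record slope across
independent replicates); image stacks of ~100 frames at 96×160 px; fiber
volumes of 48³–64³ voxels with 10 seed pairs for the density-ordering
sign test. These sizes give comfortable statistical margins for the stated
tolerances while keeping the full suite in the tens of seconds.

## Known limitations

* The bead cross-section contact-area approximation sets the absolute
  stress scale; comparisons across conditions are unaffected.
* Single-bead, in-plane (2D) tracking only; out-of-plane motion, multiple
  bound beads and bead internalization are out of scope.
* The calibration law is empirical; no magnetostatic model of the
  coil/core (hysteresis, remnant field) is included, and the saturation
  clamp is a hard cut rather than a smooth rolloff.
* Pulse-train history correction assumes each pulse's recovery mirrors its
  creep process (full reversal); materials with genuinely plastic
  per-cycle deformation violate this and are only diagnosed through the
  recovery fit.
* The synthetic fiber generator uses straight, uniform-radius tubes; its
  segmentation F1 (~0.94 at default noise) should not be read as expected
  performance on real confocal data.
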