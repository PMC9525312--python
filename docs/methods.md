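# Methods

## The measurement problem

A dividing rod-shaped bacterium concentrates its cell-wall synthesis
machinery in a ring at midcell. Single molecules of a septal protein,
sparsely labeled and imaged at 1 frame/s for 150 frames, either dwell in
place or travel around the circumference of the division plane. Because
the septum is the rim of a cylinder viewed side-on, in-plane (xy)
displacements underestimate the true motion: a molecule moving along
the circumference appears to slow down and reverse as it rounds the
visible edge. The analysis therefore (i) localizes molecules in 3D
using an astigmatic PSF, (ii) links localizations into trajectories,
(iii) unwraps trajectories onto the fitted cell cylinder, (iv) splits
them into segments classified as stationary or processive, and (v)
fits population-level speed distributions.

## Observation model (simcell)

Molecules live on a cylinder of radius 400 nm whose axis lies in the
focal plane. Stationary molecules keep a fixed (θ, l); processive ones
move along the circumference only (θ̇ = ±v/r, axial drift 0) at a speed
drawn once per run from a log-normal distribution. Defaults encode the
studied conditions: population fractions (0.55, 0.45, 0) for
stationary / slow / fast, stationary dwells exponential with mean 27 s,
runs exponential with mean 15 s, slow log-normal mean 9.4 nm/s and fast
30 nm/s (both with log-sd 0.3), 150 frames at 1 frame/s.

Observed localizations are surface points mapped to the camera frame,
perturbed by Gaussian noise (σ_xy = 30 nm, σ_z = 50 nm — plausible
placeholders exposed in `SimParams`, since the true localization
precision depends on dye and instrument), restricted to the bottom half
of the cylinder (|θ| ≤ π/2; the focal plane sits ~250 nm above the
coverslip), thinned by blinking. Blinking is a two-state telegraph
whose off-gaps are geometric with mean `blink_off_mean` frames and
whose duty cycle equals `detection_prob`. The default density of 4
molecules per movie emulates sparse (~1 nM dye) labeling; at that
density at most ~1 molecule is typically visible at a time, which is
what keeps nearest-neighbor linking valid. Crowding the septum makes
gap-closing chain distinct molecules and is the dominant artifact mode
of this class of analysis.

Astigmatic widths follow quadratic defocus curves
σ(z) = σ₀√(1 + ((z∓c)/d)²) with σ₀ = 130 nm, c = 250 nm, d = 400 nm;
σ₁ − σ₂ is strictly monotone, so the width pair determines z uniquely.
Because the refractive-index mismatch between the bead calibration path
(glass/oil) and the aqueous cell makes the apparent defocus larger than
the true depth, cell widths are drawn at z/0.75 — so that the standard
lookup (calibration z, then ×0.75) round-trips to the true z, while
bead stacks (matched path) round-trip to 0.75× the stage z.

What the generator does **not** emulate: camera physics
(Poisson-Gaussian noise, EM gain), SIM reconstruction, state switching
within a molecule's lifetime, axial wobble of processive runs, and
drift. Passing tests therefore validate the analysis chain against the
stated motion model, not against every complication of real data.

## Localization post-processing (loc3d)

Spots are fitted with an axis-aligned elliptical Gaussian (least
squares, moment-based initialization); flat or non-convergent patches
raise and are excluded. Calibration interpolates the bead width table
with cubic splines (light automatic smoothing if width noise breaks
monotonicity); z lookup minimizes
(√σ₁ᵒᵇˢ − √σ₁(z))² + (√σ₂ᵒᵇˢ − √σ₂(z))² on a dense grid with parabolic
refinement — the √σ metric is the robust standard choice — and then
multiplies by the 0.75 rescale. Widths outside the calibrated envelope
(±25% relative) return NaN and are dropped with a logged count. The
band-pass keeps 60 nm ≤ σ₁, σ₂ ≤ 300 nm, bounds inclusive.

## Tracking

Greedy global nearest-neighbor linking: per frame, candidate
(track, localization) pairs within 300 nm are accepted in order of
increasing distance (ties broken by earlier track frame, then input
order). A track survives up to 8 dark frames; the 300 nm radius is not
scaled with gap length (conservative, avoids chaining unrelated
molecules). The 300 nm/frame threshold bounds trackable motion at
300 nm/s; the implied maximum diffusion coefficient is reported under
an explicit MSD convention (r²/4Δt = 0.0225 µm²/s by default, r²/6Δt
optionally) because no single convention reproduces a rounder figure.
Septal selection keeps tracks whose mean axial position is within
200 nm of the septal plane (septum width ~100 nm plus margin).

## Geometry and unwrapping

The cylinder axis is the principal direction of the localization cloud,
refined by nonlinear least squares on the radial residuals (PCA alone
carries an O(n^{-1/2}) tilt); the radius comes from an algebraic circle
fit of the cross-sectional projection and the septum from the axial
density maximum. For simulation runs the pipeline uses the generator's
exact geometry by default (`geometry_mode="config"`); fitting requires
localizations spread along the cell, which septum-only data do not
provide. Unwrapping computes θ from the radial vector in the plane
perpendicular to the axis (equivalent to re-projecting each point onto
the cylinder surface, which confines z noise to the tangent direction),
wraps per-step increments into (−π, π] — unambiguous because ≤300 nm/s
at 1 frame/s on r ≥ 300 nm gives |Δθ| < π — and accumulates
s = r·unwrap(θ). Points closer than 0.2 r to the axis are dropped
(angle ill-defined). Arc length always dominates the in-plane chord,
and on zero-noise tracks the unwrapped slope equals the programmed
speed to machine precision.

## Segmentation and classification

s(t) is split by recursive binary changepoint search: every interior
breakpoint leaving ≥6 points per side is tested and a split is accepted
when it lowers the Gaussian-residual BIC (3 extra parameters per
split). This replaces the manual segmentation of the original protocol;
manual index ranges can be passed to bypass the search.

Each segment is fitted with a line; Δ is the fitted rise over the
segment. Two statistics decide the label:

* **R = stdev(residuals)/|Δ|.** Small R means displacement dominates
  noise. (Stated the other way around — displacement over residuals —
  the published threshold "R ≤ 0.4 ⇒ processive" would be inconsistent;
  this package fixes the orientation so that the printed threshold
  semantics hold.)
* **P**, the probability of processive movement, computed as a seeded
  residual-permutation test with B = 200 surrogates built around the
  zero-slope (mean) model: P is the fraction of surrogates whose
  absolute net displacement is smaller than |Δ|. The original statistic
  is defined in prior-work supplements not reproduced here; the
  permutation test is a declared substitute with the same threshold
  semantics (P ≥ 0.5 ⇒ directional).

Processive ⇔ R ≤ 0.4 **and** P ≥ 0.5, both inclusive. |Δ| below 1 pm is
treated as exactly zero (stationary by construction). Segments of ≤5
frames are reported but not classified.

**Known bias.** At σ_loc = 30 nm and v ≈ 9.4 nm/s, R ≤ 0.4 requires
vT ≳ 2.5 σ_loc, i.e. runs of at least ~8 s. With exponential 15 s runs
truncated at >5 frames, ~18% of processive segments are shorter and are
misclassified as stationary, inflating the recovered stationary share
by ~7 points on isolated segments — and by ~15–18 points through the
full pipeline, where the z-lookup adds up to ~67 nm of tangential noise
on the cylinder sides. The same selection effect inflates the mean
speed of short accepted segments (folded-noise bias, ~+30% end to end
under default noise). Both vanish with noise off, which is how the
end-to-end integration test pins the chain down exactly.

## Population fits

The empirical CDF of processive speeds (plotting positions
(i − ½)/n) is fitted by bounded least squares with one or two
log-normal components; components are ordered slow-first and the mean
speed of a component is exp(u + σ²/2). Model selection ("auto")
compares BICs computed from the **sample log-likelihood** of the fitted
mixture density and requires an improvement of ≥6 to accept the second
component; a Gaussian BIC on ECDF residuals is not used because those
residuals are strongly autocorrelated and always favor the larger
model. Standard errors come from resampling the speeds with replacement
(B = 200, seeded), refitting each replicate initialized at the
full-sample solution; failed replicates are dropped and counted, >20%
failures raise. (Resampling speeds, rather than CDF points, is the
declared reading of "bootstrapping the CDF curves".)

Stationary apparent speeds are histogrammed from 0 in 2 nm/s bins
(widths were not published; 2 nm/s resolves the 0–15 nm/s range) and
fitted with A·e^(−λx); u = 1/λ is the mean apparent speed.

## Ring statistics

The circumferential ACF implements the printed non-circular pair sum
p(r_k) = Σ_{i=1}^{N−k} Z_i Z_{i+k} / Σ Z_i² literally, so p(r₀) = 1 and
p decays with lag; a circular (wrap-around) variant is available behind
a flag, since a ring is topologically periodic but the stated formula
is not. Default binning is 72 bins (5°, ~25 nm of arc at r = 300 nm,
below the ~50 nm lateral resolution). Ring dimensions: diameter from a
circle fit in the ring plane; width (axial) and thickness (radial) as
FWHM of Gaussian fits to the projected distributions, deconvolved by
quadrature subtraction of the imaging resolution (defaults 50 nm xy,
80 nm z, interpreted as FWHM); a measured width at or below the
resolution returns 0 or the raw value with a warning flag rather than
an imaginary number. The pseudo time course orders rings by decreasing
diameter (constriction as a proxy for time) and bins the midcell
fraction.

## FRAP

Normalization follows the half-ring recipe: divide by the
outside-septum reference scaled to its first frame (global
photobleaching correction), then map the first post-bleach frame to 0
and the late average (last 20 frames) of the opposite half-ring to 1.
Recovery is fitted with F(t) = F∞ − Σⱼ aⱼ·e^(−t ln2/τⱼ) with
independent amplitudes (one or two phases; "auto" uses the ≥6
log-likelihood-BIC rule), multi-start over a τ grid. The fast phase is
compared against the free-diffusion timescale A/D (≈2.5 s for a 0.1 µm²
half-ring at D = 0.04 µm²/s); the slow phase matches the time for a
processive cluster to cross the ~500 nm illumination field
(500/8.8 ≈ 57 s).

## Kymographs

Per frame: mean-normalize (photobleaching), bicubic-resample to
20 nm/px, average across an 11-interpolated-pixel (~200 nm) line, then
a 4-frame moving average along time (same-length output). Speeds come
from the per-row intensity-weighted centroid of the
background-subtracted stripe, fitted with a least-absolute-deviations
line (replacing manual slope reading, for reproducibility; a manual
two-point reader is provided); rows without sufficient contrast return
"no directional cluster".

## Problem sizes and determinism

All stochastic routines take explicit seeds and are bit-reproducible.
The shipped test and acceptance workloads use 400 isolated segments for
classifier recovery, n = 1000 speeds with a 200× bootstrap for the
mixture fit, 40–50 simulated cells for end-to-end runs, 150 s FRAP
traces and 60-frame movies — sizes chosen to estimate each quantity
with standard errors comfortably inside the stated tolerances.
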