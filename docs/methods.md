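# Methods

This note documents the models implemented in `spindlenematic`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.  All lengths are in μm, retardance in nm, angles in
rad; nematic angles are defined mod π and all angle arithmetic happens
in the doubled-angle representation exp(2iθ).

## Spindle geometry: the pole-indented tactoid

The spindle silhouette is parameterized by (L₀, R₀, r₀): a convex
"belt" circle through the virtual poles (±L₀, 0) with apex (0, ±R₀)
— center (0, c), c = (R₀² − L₀²)/2R₀, radius √(L₀² + c²) — and concave
polar caps of radius r₀ centered on the virtual poles.  The planar
region is the belt lens minus the two cap disks; the 3D body is its
solid of revolution about the long axis, so cross sections near the
poles are annuli and the projected silhouette extends slightly past the
planar curve around each polar bite.

Fitting is nested and deterministic: an outer 1D search over L₀ (grid
of 80 values over [1.02, 4] × the maximal boundary radius, then a
bounded scalar refinement), and for each L₀ an inner loop that
alternates algebraic circle fits with sector reassignment.  Points are
folded into the first quadrant (full mirror symmetry is enforced; the
option of fitting left/right caps independently was considered and
rejected — on synthetic data the symmetric fit is strictly better
conditioned and the asymmetry of real spindles is already absorbed by
the registration rotation).  Cap seeds of 5°, 15°, 25° and 45° half
width are all tried and the converged assignment with the lowest summed
squared radial residual wins; thin caps need narrow seeds, fat caps wide
ones.  A boundary that a plain circle fits as well as the four-arc model
(residual standard deviation of b(ϕ) below twice the model rms) is
flagged `degenerate` rather than silently returned: circles and ellipses
are the r₀ → 0 degeneration of the model family and carry no cap
information.

Boundary extraction follows the standard recipe — background
subtraction (median of the four 5×5 corners), Gaussian smoothing,
radial gradient maxima in 1° polar bins with parabolic sub-sample
refinement — with one caveat worth knowing: on Abel-projected retardance
the edge profile rises as √(distance inside), so the gradient maximum
sits systematically inside the true silhouette by roughly the smoothing
length.  Fitted L₀ from images is therefore biased low by ~5–10%
relative to generator truth; this is a property of the modality (the
boundary-level fit round-trips exactly) and all image-level tests assert
recovery at the 10% level while boundary-level tests assert sub-percent
recovery.

## The circle-arc director field

With strong anchoring, the interior director is tangent to the unique
circle through (x, y) and both virtual poles:

    θ(x, y) = atan2(−x, y − c),   c = (x² + y² − L₀²) / 2y,

with θ = 0 on both axes and singularities only at the virtual poles.
The field satisfies θ(−x, y) = θ(x, −y) = −θ(x, y) exactly, and on the
convex boundary it coincides with the boundary tangent — the anchoring
prediction η(ϕ) (tangent on the belt, cap-normal on the caps) is the
boundary trace of the same construction.  Angle averaging uses
½ arg Σ e^{2iθ} (degenerate when the resultant vanishes, e.g.
{π/4, 3π/4}); pooling across spindles rescales r → r/L₀ and folds
fields into the first quadrant with the odd-symmetric four-point
combination [θ(x,y) − θ(x,−y) − θ(−x,y) + θ(−x,−y)]/4, which also
suppresses uncorrelated noise by a factor of 2.

## Synthetic data

The generator is the study-conditions reference for every test.
Defaults: L₀ = 15.2, R₀ = 8, r₀ = 4 μm; microtubule density
ρ₀ = 50 μm⁻² (with the per-microtubule retardance constant A₀ = 7.5 nm²
this gives a central retardance of 6 nm, the few-nm scale of real
recordings); pixel 0.25 μm; frame interval 3.6 s (≈500 frames / 30 min
acquisition pace); additive retardance noise 0.1 nm.

Retardance is rendered analytically per pixel as A₀ ρ₀ × the
optical-axis chord through the revolved tactoid minus void interiors
(1 nm² μm⁻² μm = 10⁻³ nm); rigid drift is applied by inverse-mapping
pixel coordinates before evaluation, so drifting movies carry no
resampling error.  Voids are "tactoid-like": a circle-arc width profile
of chord β revolved about the axis and scaled anisotropically so the
plate cross section is an (a, b) ellipse; the default population is
n_chr = 20 voids of length β = 11 μm and geometric-mean waist
√(ab)·2 = 1 μm with a/b = 2.5, placed sterically in a 6.5-μm plate
disk.  Voids must lie strictly inside the body (validated by surface
sampling).

The slow axis is the circle-arc field plus an orientational fluctuation
field built by spectral filtering of white noise (equal-time spectrum
∝ |q|^ε, default ε = −2, the active-nematic scaling), with an AR(1)
(discrete Ornstein–Uhlenbeck) temporal kernel (default correlation time
10 s; the temporal statistics are a modelling choice, not an observable
we match).  Inside voids the fluctuation amplitude is multiplied by
`void_boost` (default 1.07) through an envelope smoothed by 0.25 μm:
a sharp binary envelope would inject broadband high-wavenumber power
that real, smooth enhancements do not have, burying the spectral peak
the boosted voids are supposed to create.

What the generator does **not** emulate: photorealistic optics (a
single Gaussian PSF stands in for the imaging response), cytoplasmic
background, out-of-plane spindle rotation, chromosome internal texture,
per-void individuality of the fluctuation boost, and any coupling of
density to the director beyond the voids themselves.  Passing tests
therefore demonstrate correctness of the *analysis* under the stated
statistical structure, not robustness to every property of real
micrographs.

## Registration

Four steps: optional ROI crop; per-frame translation from the center of
brightness of the largest component of the blurred (σ = 1.5 μm),
thresholded (half the 99.9th percentile — the robust version of "half
maximum") retardance; a single movie-wide rotation from the nematic
mean slow axis (rotating raster and angle values together through the
doubled-angle components, which avoids averaging across the branch
cut); and a per-frame refinement aligning gradient-magnitude images to
a 10-frame moving-average reference by phase correlation with 1/20-px
upsampling, falling back to the translation estimate with a warning if
the refinement shift exceeds 5 px.  All transforms are composed and
applied in a single bilinear resample.  Synthetic benchmarks: injected
drifts of several px/frame recover to < 0.1 px, rotations of 5° to
< 0.4°, and registration is idempotent to < 0.3 px.

A related acquisition-time bound: keeping the out-of-plane component of
the spindle axis below 0.1 caps the relative retardance error of the
squared-cosine projection law at 1%.

## Fluctuation spectra

δn_y ≈ θ(r, t) − θ_arcs(r) over a centered box of side λ₀ = 8 μm
(a warning fires if the time-mean angle exceeds 15° anywhere, where the
small-angle identification degrades).  Transforms mirror-pad all three
dimensions (doubling each by default), use the physical normalization
c_nn = |δñ_y|²/(τ₀λ₀²) with padded extents so that
Σ_q s_nn (Δq/2π)² equals the real-space variance exactly, integrate
over ω by trapezoid (with the periodic endpoint restored), and discard
|q| > 2π/λ_im (λ_im = 0.530 μm).  Two non-obvious numerical choices:

* The fixed-q_x slice is reported only at modes commensurate with the
  unpadded box (multiples of 2π/λ₀): mirror padding halves the mode
  spacing, but the interleaved half-modes are interpolates carrying a
  systematic even/odd alternation, not data.  Padding wider than
  doubling tiles the box coherently, growing commensurate-mode power
  quadratically in the copy count; the spectrum is rescaled by the
  squared copy count so it is padding-width invariant (verified to
  machine precision).
* Peak detection models the background as the exact fixed-q_x slice of
  an isotropic inverse-square spectrum, C/(q₀² + q_y²) (which is what
  "decays as q_y⁻²" looks like at finite q₀), fits C to the three
  lowest and highest modes, and accepts the largest *relative* residual
  that is also a local maximum of the slice itself and exceeds 4× the
  residual MAD.  Spectral estimates carry multiplicative noise, so the
  relative residual has uniform variance; the raw-local-max requirement
  guarantees a monotone slice never yields a peak.  Single short noisy
  stacks can still false-alarm at the ~10–20% level — peak statistics
  are meaningful per ensemble, as in practice where spectra are averaged
  over spindles.

Density–fluctuation coupling: local adaptive binarization (pixel ≥ mean
over a 2-μm disk, edge disks clipped to the image) splits the box into
low/high-density classes; the statistics are the least-squares slope of
⟨|δθ|⟩_t against ⟨r⟩_t and the ratio of mean |δθ| between classes.  At
movie level the binarized classes align only partially with void
footprints (the global Abel profile dominates the retardance
landscape), so the measured ratio understates the in-void enhancement —
per-spindle values scatter by ±3–5%, matching the spread seen in real
per-spindle histograms; recovery of the generator's boost to ±0.03 is
only meaningful when the low-density class coincides with the boosted
region, which the field-level tests arrange by construction.

## Void-profile inversion

Per column, the default estimator ("support" mode) takes the radius
R(x) from the sub-pixel edge of the suprathreshold region (smoothed by
1.2 px, threshold 10% of the column peak, with a two-pass correction
for the √-shaped edge) and the density from the column integral:
ρ_x = ∫r dy / (A₀·10⁻³·πR²), which recovers the *mean* cross-sectional
density exactly for any interior void arrangement.  The naive joint
least-squares fit of (amplitude, R) — kept as mode "free" — couples R
to interior structure: a central deficit flattens the profile, inflates
R by ~2–3%, and overestimates missing density by ~50% relative; both
modes agree on void-free columns to 0.5%.  ρ_x is normalized by the
mean of its top decile (the near-pole plateau, robust to noise) and the
profiled region should exclude |x| > L₀ − r₀ where cross sections
become annular and the filled-disk projection no longer applies.

Void fractions: plate-area fraction 1 − ρ_x(0); volume fraction
1 − Σρ_x πR²/ΣπR².  The average void shape divides the missing area by
n_chr = 20, converts to an effective diameter d(x) = 2√(A/π), and fits
the circle-arc width profile d(x; w, β) with
ρ_c = β²/4w + w/4 (the sagitta relation, unit-tested against the
three-point circle).  On synthetic spindles the waist is recovered
within a few percent across cross-section aspect ratios 1–4 at fixed
area — the geometric-mean interpretation of the waist holds by
construction of the area attribution.

## Metaphase-plate analysis

Reslicing finds the chromosome channel's intensity-weighted principal
axes and resamples the stack so the smallest-variance direction becomes
the image normal (error on synthetic 30° tilts: < 0.1°); an isotropic
distribution is refused.  Segmentation is the stated chain — Gaussian
blur (σ = half the quoted filter radius), local adaptive binarization
(radius 1.5 μm), erosion by a 0.4-μm disk, 4-connected components, the
19–20-section acceptance rule returned rather than applied — with two
additions: components below 0.1 μm² are dropped (erosion-surviving
noise cores), and each labelled seed is grown back over its binarized
footprint by nearest-seed partition, because the erosion exists to
*separate* touching sections and measuring on eroded footprints would
bias every size low.  Mean-threshold binarization inflates footprints
by the blur halo, so pixel-count areas overestimate; unbiased sizes
come from intensity-weighted moments with the blur variance subtracted,
or from the integrated intensity over the footprint plus a 0.6-μm halo
(exact for blurred unit indicators; recovers synthetic section areas to
1%).

The pair correlation normalizes radially binned FFT autocorrelation
pair counts of the mask by those of the boundary mask and by ⟨I⟩²
(0.1-μm bins).  This removes boundary-shape trends exactly — uniformly
random fills read 1 at every separation — and g(0) = 1/fill-fraction
for binary masks.  For simulation ensembles two optional refinements
exist: normalization against the uniform-placement coverage map or the
replicate-mean mask (centers cannot sit within an ellipse-size margin
of the boundary, so even interaction-free ensembles are centrally
dense; the flat-boundary estimator then shows a ~0.1 trend hump at
2–5 μm that is one-point density structure, not pair ordering),
together with the canonical finite-N factor n/(n−1).  Extremum
detection smooths by 3 points, requires the first interior minimum to
lie beyond the point where g drops below g(0)/2 (past the within-section
shoulder), refines locations by parabolic interpolation (0.1-μm bin
quantization otherwise dominates the uncertainty), and accepts a
min/max pair only if its contrast exceeds 0.15: interaction-ordered
ensembles modulate g_II by ≳0.25 while steric packing texture stays
below ~0.1, so the gate separates ordering from residual texture.
Uncertainties are bootstrap SDs over spindles/replicates (1000
resamples by default).

## Defect-quadrupole model

One void = two −½ defects at (±β/2, 0) and two +½ defects at (±p, 0)
in a far-field-aligned 2D nematic; each defect contributes a harmonic
angle field, so the superposition solves the one-constant Frank
Euler–Lagrange equation and the void boundary *emerges* as the
separatrix streamlines through the −½ defects.  The local three-fold
structure at a −½ defect puts the upper separatrix at exactly 120°, so
tracing is a fixed-step RK4 integration (step β/400) of the unit
director with sign continuity, ended at the axis or the opposite
defect; closure within β/100 is enforced.  The lens width is monotone
decreasing in p (verified numerically over the full range), so p is
solved from the requested width D by bisection.

The two-void interaction uses rigid superposition (the defect geometry
is not re-solved at each separation; at d ≲ β mutual deformation would
modify it, which is the main caveat of the model) and the charge-neutral
cross-pair sum U_int/k = −2π Σ k_i k_j ln r_ij — exactly the Frank
cross term, verified against direct numerical integration of
∇θ_A·∇θ_B over a large box to 0.1% (samples closer to a core than half
a grid step are excised; the singularity is integrable and its angular
average vanishes, but an arbitrarily close sample would inject
unbounded quadrature error).  The energy prefactor convention (−2π k
per ln) only rescales U/k; the d⁻⁴ far-field slope, monotonicity and
Monte Carlo configurations are invariant to it.

## Monte Carlo placement

Hard (a, b) = (2.1, 0.8) μm ellipses in a disk of radius 6.5 μm (sized
so 20 sections cover ≈20% of the plate).  Overlap is decided by an
exact algebraic test — affine map sending one ellipse to the unit
circle, then a Lagrange-multiplier bisection for the point-to-ellipse
distance — and boundary containment by the analogous farthest-point
root; both are numba-compiled, as is the Metropolis kernel
(single-ellipse translation ±0.4 μm / rotation ±0.5 rad moves, hard
constraints rejected outright, geometric temperature schedule from 100
to 1 over 400 sweeps of 20 moves).  Interaction distance is
center-to-center.

The repulsion amplitude is the one genuinely free constant (the
experimental reference fitted it).  The default calibration sets the
pair energy to kT_final at s = 2b = 1.6 μm, twice the minor axis — just
beyond side-by-side contact — making the repulsion decisive (~10 kT) at
contact range and a weakening bias toward the coordination shell.  The
choice sits on a plateau: extremum locations are flat over a 4×
amplitude range around it (minimum 1.33 ± 0.01 μm, maximum
2.55 ± 0.03 μm at 200 replicates).  Much stronger coupling (≳50×)
freezes an expanded near-lattice with correlations at 1.55/2.95 μm and
no rim ring; much weaker coupling degenerates into bare packing
texture peaking near 2.8 μm.  Ordered ensembles show the characteristic
structure of the experimental plates: an outer ring of ~13–15 mostly
radially oriented ellipses and interior g_II extrema near 1.33 and
2.55 μm, at the same locations for all four repulsive potentials.

Ensemble sizes were chosen so each headline quantity is statistically
stable at a few-minute single-CPU cost: 200 replicates reproduce
extremum locations to ±0.03 μm across seeds, and the acceptance script
and tests both use that size.

## Known limitations

* Image-level geometry fits inherit the inward gradient-edge bias of
  Abel-projected intensity (~5–10% on L₀); comparisons across
  modalities should use the same extraction.
* The fluctuation generator's boost is a variance modulation; it does
  not model hydrodynamic coupling between voids, so inter-void
  correlations beyond the imposed geometry are absent.
* The 2D quadrupole interaction uses rigid superposition; near-contact
  separations (d ≲ β) would require re-solving the mutual defect
  geometry.
* The steric null retains genuine random-sequential-adsorption contact
  texture in g_II at the ≲0.1 level; it is below the ordering
  prominence gate but not zero.
* Pixelated-section placement (`random_placement_sections`) is a
  straightforward rejection sampler and becomes slow for dense packings
  of large sections.
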