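# spindlenematic

Quantitative analysis of the microtubule network of metaphase-II oocyte
spindles as a nematic liquid crystal, and of the long-range repulsion
between chromosomes that the nematic field mediates.

The package is aimed at quantitative cell biologists and biophysicists
working with label-free polarization microscopy (LC-PolScope) and
confocal imagery of spindles.  It implements, end to end:

* **Spindle morphometry.**  The spindle silhouette is modelled as a
  *pole-indented tactoid*: two convex circle arcs through virtual poles
  at (±L₀, 0) with apex height R₀, indented at each pole by a concave
  cap of radius r₀.  Boundaries are extracted from time-averaged
  retardance by radial gradient maxima and fitted by nested algebraic
  circle fits with iterated convex/cap sector assignment.
* **The circle-arc director field.**  With strong anchoring (tangential
  on the convex surface, normal on the caps), the interior director lies
  tangent to the unique circle through (x, y) and both virtual poles:
  θ(x, y) = atan2(−x, y − c), c = (x² + y² − L₀²)/2y.  The model has no
  free parameters once L₀ is fitted; rescaling r → r/L₀ collapses
  different spindles onto one master field.
* **Orientational fluctuation spectra.**  δn_y ≈ θ(r, t) − θ_arcs(r) in
  a centered box, mirror-padded (2+1)D Fourier transforms, the
  equal-time correlation s_nn(q) = (1/2π)∫c_nn dω with a diffraction
  cutoff at |q| > 2π/λ_im, and peak detection on the s_nn(q₀, q_y)
  slice above the inverse-square background of a homogeneous active
  nematic.
* **Void-profile inversion.**  Each retardance column is the Abel-type
  projection r(x, y) = 2 A₀ ρ_x(x) √(R(x)² − y²); inverting it gives the
  axial density profile ρ_x(x), void volume/plate-area fractions, and —
  attributing the missing density to n_chr identical voids — the average
  void width profile, fitted by a circle arc of chord β and waist √(ab).
* **Metaphase-plate statistics.**  Reslicing of two-channel confocal
  stacks to the chromosome best-fit plane, the blur → local-adaptive
  binarization → erosion segmentation chain, second-moment ellipse
  summaries, and the edge-corrected pair correlation
  g_II(s) = ⟨I(r)I(r′)⟩/⟨I⟩² with bootstrap uncertainties on its
  extrema.
* **Defect-quadrupole theory.**  A 2D void as a charge-neutral
  quadrupole (two −½ defects at the tips, two +½ inside), its emergent
  separatrix boundary, and the void–void interaction
  U_int(d)/k = −2π Σ k_i k_j ln r_ij, repulsive at all separations and
  ∝ d⁻⁴ in the far field.
* **Monte Carlo chromosome placement.**  Hard-ellipse packing (exact
  algebraic overlap tests, numba-compiled) with steric-only random
  placement or annealed Metropolis dynamics under s⁻⁵, s⁻³, Yukawa, or
  the 2D quadrupole repulsion, pushed through the same g_II pipeline as
  image data.
* **Synthetic ground truth.**  A generator that renders PolScope movie
  pairs (retardance nm / slow axis rad) and plate images from known
  geometry, density, fluctuation statistics, drift and noise — every
  analysis stage is validated against it.

## Worked example

Simulate a drifting spindle movie, register it, and fit its geometry:

```sh
python -m spindlenematic simulate-spindle --out demo --frames 8 --n-voids 12 --seed 3
python -m spindlenematic register --in demo --out demo_reg
python -m spindlenematic fit-geometry --in demo_reg --out demo_fit.json
python -m spindlenematic voids --in demo_reg --out demo_voids.csv
python -m spindlenematic quadrupole --out demo_quad.csv --beta 11 --D 1
python -m spindlenematic mc --out demo_gii.csv --replicates 10 --seed 1
```

which prints (numbers from this exact run):

```
wrote demo_retardance.tif / _slowaxis.tif / _truth.json
registered 8 frames -> demo_reg_*
L0=13.84 R0=7.32 r0=2.53 rms=0.113 um
volume fraction 0.036, plate fraction 0.050, waist 0.79 um, beta 11.7 um
p=5.167 um; far-field log-log slope -3.980; wrote demo_quad.csv
g_II min 1.34 +- 0.023; max 2.77 +- 0.132; wrote demo_gii.csv
```

Reading the output: the fitted virtual-pole half-spacing L₀ = 13.8 μm is
biased ~9% below the generating 15.2 μm because the gradient maximum of
an Abel-projected (square-root-edged) retardance profile sits slightly
inside the true silhouette — the same bias the imaging modality itself
carries.  The twelve 11-μm-long voids occupy ~4% of the spindle volume;
the average void profile comes back as a circle arc of chord 11.7 μm.
The defect-quadrupole interaction decays with the aligned-quadrupole
exponent −4, and a 10-replicate Monte Carlo ensemble of repulsive
ellipses already shows the depletion ring (g_II minimum at 1.34 μm) and
coordination shell (maximum at 2.77 μm, still noisy at 10 replicates);
the 200-replicate
ensembles used for headline numbers pin these down much more tightly.

Equivalent library calls live in `spindlenematic.*`; every CLI command
is a thin wrapper over one or two functions.

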