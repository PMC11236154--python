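# Methods

## Shape representation: elliptic Fourier descriptors

A closed head outline, traversed counterclockwise at constant speed along
its perimeter `T`, is expanded as a truncated elliptic Fourier series:

    x(t) = A0 + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T)
    y(t) = C0 + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T),   n = 1..H

Coefficients are computed from the polygon's exact segment lengths (chain
parameterization) rather than pixel chain codes, because contours arrive
as sub-pixel polygons from marching squares. With the default `H = 20`
the flattened code `(a1, b1, c1, d1, …, d20)` has 80 entries; the DC
offsets `A0, C0` carry translation and are excluded from the code.

Note that the series is taken in *arc length*: for a 2:1 ellipse the first
harmonic is `(1.8284, 0, 0, 1.0730)`, not `(2, 0, 0, 1)` as under the
angle parameterization, and odd higher harmonics are small but nonzero.
Tests therefore compare against a dense trapezoid-quadrature Fourier
oracle rather than the angle-parameterized closed form.

### Normalization

The Kuhl–Giardina procedure removes the four nuisances in order:

1. **Starting point.** The phase
   `θ1 = ½·atan2(2(a1b1 + c1d1), a1² + c1² − b1² − d1²)` rotates the
   traversal start onto the first-harmonic ellipse's major axis; harmonic
   `n` is right-multiplied by a rotation of `n·θ1`.
2. **Orientation.** `ψ1 = atan2(c1′, a1′)` is removed by left-multiplying
   every harmonic by the rotation `−ψ1`.
3. **Scale.** All coefficients are divided by the post-rotation `a1`
   (the semi-major axis), making `a1 = 1` exactly.
4. **Translation** is already absent from the code.

`θ1` is only determined modulo π; the residual two-fold ambiguity
(`θ1` vs `θ1 + π`) leaves the first harmonic unchanged but flips the sign
of every even harmonic. Because orientation is removed with a full-range
`atan2`, both branches end with `a1 > 0`, so the sign of `a1` cannot
break the tie. Instead both candidate codes are computed and the first
entry at which they differ by more than 1e-6 decides (larger wins). The
rule is invariant to O(1e-9) numerical noise, so rotated, scaled,
start-shifted and translated copies of one contour map to identical codes
(the invariance suite asserts agreement below 1e-6 over random
similarity transforms). For point-symmetric shapes the branches coincide
and the pick is a no-op.

**Chirality is not normalized by default**: a mirrored head has the same
entries up to a sign pattern, and hook handedness is biologically
meaningful. `canonical_chirality=True` additionally normalizes over the
mirror image (same branch-pick rule) for slides of unknown flip.

Three entries of the 80-vector are near-constant after normalization
(`a1 = 1`, `b1 = c1 = 0`). They are kept so the code length stays 4H;
PCA centering removes them from the analysis.

### Reconstruction and convergence

`reconstruct` evaluates the truncated series at uniform parameter values.
Reconstruction error is non-increasing in `H` (Fourier truncation); for a
256-point synthetic head the symmetric Hausdorff distance at `H = 127`
(the Nyquist ceiling for 256 samples) is ≈ 0.03 px.

## Shape PCA and mean shapes

Covariance PCA (mean-centered, unscaled) over the per-specimen codes: all
entries share units (px of the size-normalized contour), and correlation
scaling would inflate the near-constant normalization residuals. Loadings
come from the SVD of the centered matrix; signs are fixed by making the
largest-magnitude entry of each loading positive, so refits are
bit-reproducible. Two components are retained by default.

The "mean shape" of component `k` at `m` SD is the inverse Fourier
reconstruction of `mean + m·√(λₖ)·loadingₖ`; shapes are drawn at 0 and
±2 SD by default.

## Synthetic head populations

The generator emulates the two axes of variation that outline PCA
separates in murine sperm heads — head width and hook geometry — with a
minimal radial family: a superellipse body profile (exponent 2.5,
semi-axes `body_length/2`, `body_width/2`) plus an asymmetric Gaussian
bump of height `hook_length` at polar angle `hook_angle` (side widths
0.38/0.20 rad divided by `hook_sharpness`, giving the falciform
asymmetry). The radius is a single-valued positive function of angle, so
every contour is a simple CCW polygon by construction. Boundary noise is
radial Gaussian jitter smoothed with a periodic binomial kernel.
Per-specimen parameters are drawn from normal distributions truncated at
±3 SD and clipped at physical bounds.

Default head: body 60 × 32 px, hook 18 px — proportions of a cauda
epididymal mouse sperm head at ≈ 0.2 µm/px. Rendered stains are binary-ish
uint16 channels: head mask, nuclear channel with dark vacuole disks
(radius 4 px, placed by rejection sampling fully inside the eroded head,
non-overlapping, ≤ 100 attempts each), and an acrosome crescent covering
a perimeter fraction (default 0.45) of the anterior (hook-tip) end.

What the generator does *not* emulate: optical blur, shot noise, uneven
staining, touching cells, 3-D head tilt, or the real covariance structure
of genotype differences. Passing recovery tests therefore shows the
*computational chain* is correct and well-conditioned, not that real
images would be segmented this cleanly.

### Hook-recovery study conditions

The planted-signal experiment uses two populations of n = 100 heads,
identical except for the hook-length mean (separation 2 within-group SD):
hook SD 1 px (≈ 6% CV), head-width SD 1.5 px, boundary noise 0.3 px,
hook at the apical pole (`hook_angle = 0`). Two properties of the shape
family motivated the last choice, found while designing the experiment:
an off-axis hook rotates the best-fit first-harmonic ellipse as it grows,
so the normalization frame turns with hook length and the coefficient
response becomes strongly curved (no single linear PC can track it); and
body-*length* variation is nearly collinear in coefficient space with
on-axis hook growth (both stretch the aspect ratio), so it is held fixed
within groups. Under these conditions one of two retained PCs correlates
with ground-truth hook length at |r| ≈ 0.85–0.91 and the group contrast
on that PC is significant at p < 0.001; with zero separation the
false-letter rate over 200 replicates stays below 10%.

## Stain measurements

* **Acrosome area**: Otsu (or fixed) threshold of the PNA channel inside
  the head mask dilated by 2 px; area = positive pixels × pixel_size².
* **Vacuoles**: connected dark components inside the 1 px-eroded head,
  intensity < (1 − 0.5) × median head intensity, area in [4 px²,
  25% of head area]. The defaults exclude single-pixel noise and
  whole-head dropouts.
* **Prevalence**: share of heads with ≥ 1 vacuole, Wilson 95% interval.

Both measurements use relative criteria and are invariant to image-wide
affine intensity rescaling; absolute staining units are not comparable
across instruments, so only group contrasts are interpreted.

## Kinematics

Standard CASA definitions on uniformly sampled 2-D tracks: VSL (net
displacement / time), VCL (polygonal path length / time), VAP (path
length of the smoothed trajectory / time). Smoothing is a centered moving
average, default window 5 frames, with the window shrinking symmetrically
at the ends so the smoothed path keeps the raw endpoints. This makes
`VCL ≥ VAP ≥ VSL` a theorem (each smoothed increment is a convex
combination of raw increments whose weights telescope to one; any path
majorizes the straight segment between its endpoints), and it is also
asserted as a property over random walks. The motility call (default
VCL ≥ 25 µm/s) is a documented stand-in for instrument-internal criteria,
which are proprietary.

## Group statistics

Two groups: unpaired two-tailed Student's t (pooled variance; Welch
optional). More groups: classical one-way ANOVA, then each knockout
compared with the wild-type control — Dunnett's many-to-one procedure by
default (Holm-adjusted pairwise t available), since control-anchored
letters next to an omnibus ANOVA are the convention in this literature
and the exact post-hoc used with such reports is rarely stated.
Comparison p-values map to letters: a (p < 0.05), b (p < 0.01),
c (p < 0.001), most extreme applicable.

Degenerate inputs use documented conventions instead of raising: zero
within-group variance with equal means → p = 1; with unequal means →
F = ∞, p = 0. Dunnett's p is evaluated by stochastic multivariate-t
integration, so a fixed internal rng keeps reports byte-reproducible.

## Numerical choices

* Contour coordinates are Cartesian y-up (`y = n_rows − 1 − row`);
  boundaries are the 0.5 iso-contour of the mask (marching squares,
  sub-pixel); all contours are CCW (positive shoelace area).
* Equal-arc resampling iterates to a fixed point (movement < 1e-12,
  ≤ 50 passes): a single pass leaves spacing non-uniformity of the order
  of the squared turning angle, and the iteration makes resampling
  idempotent.
* Normalization residuals are asserted at 1e-9 on exact-friendly inputs
  and 1e-6 on noisy ones; branch/chirality ties break at 1e-6.
* Default contour density is 256 points (Nyquist-safe for H = 20);
  population experiments use 200 points and images of 160 × 160 px to
  keep full runs fast.
* Contour CSVs round-trip bit-exactly (repr on write, round-trip float
  parsing on read), which is what makes repeated pipeline runs
  byte-identical.

## Known limitations

* The hook model is a radial bump, not a curved spline: it cannot
  represent recurved hooks whose tip points backwards past ±90°, and
  `hook_length` interacts mildly with measured body proportions.
* PCA is linear; large hook ranges trace a curved path in coefficient
  space and split across components (see study conditions above).
* Vacuole detection assumes roughly uniform nuclear staining; graded
  intensity would need background modelling.
* Acrosome quantification reports area only, not the reacted/intact
  classification used with immunostaining.
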