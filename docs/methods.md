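# Methods

This note records the model, the numerical choices and the design decisions
behind `capadh`, and what the synthetic validation does and does not
demonstrate about real laboratory data.

## The measurement model

**Geometry.** The meniscus raised by a small tip withdrawn from a liquid
bath is treated as axisymmetric, and its meridian is approximated by the
elliptic profile `y(x) = b sqrt(1 - (x/a)^2) + c` on `[r_tip, a]`.  This is
a fitting model, not a solution of the Young–Laplace equation: it is chosen
because it tracks observed silhouettes well with three parameters and
integrates cheaply.  Solving the true equilibrium shape is out of scope by
design.  The algebraic form is isolated in a single function
(`geometry._elliptic_meridian`) so it can be swapped without touching
anything else.  The profile meets the bath at radius `a`; the offset `c`
absorbs any residual baseline mismatch and should come out near zero for a
well-normalized fit — it is fitted freely and reported rather than
constrained, so a systematic mismatch is visible instead of hidden.

**Energy and force.** Per frame, the energy to build the meniscus is the
added surface energy `sigma (A - A_flat)` plus the constant tip–liquid
contact term `sigma* A_contact`.  The adhesion force is `F = dE/dy` at the
snap-off frame, where `y` is the tip height.  Two discretizations are
provided: a backward two-point difference and (default) a one-sided
three-point stencil on non-uniformly spaced samples, exact for quadratic
`E(y)`.  Energies are pivoted at the snap-off frame before differencing so
additive constants — the unknown `sigma*` term — cancel without
floating-point cancellation loss.  The estimator is therefore independent
of `sigma*` by construction, which is verified by test rather than assumed.

**Elongation and stiffness.** The elongation released at snap-off is
measured between the snap-off frame and the first relaxed frame:
`dy = (tip_after - tip_at_snap) - (stage_after - stage_at_snap)`, positive
when the structure was stretched.  `D = F/dy`.  The force–elongation curve
uses the same derivative estimator per frame and reports a least-squares
slope (an independent stiffness estimate) and R² as a linearity check of
the Hookean assumption.

**Bending mode.** For a fiber clamped at one end and pulled down at the
other, the end-slope relation of a linearly elastic cantilever with
circular cross-section is inverted:
`E_Y = 32 F l^2 / (pi d^4 sin(alpha))`, with the force projected onto the
beam normal by `cos(tilt)` for a tilted mount (default 0).  Whether the
end-slope term should be `sin` or `tan` of the measured angle is not
decidable from first principles at small angles; both are implemented and
selectable (`angle_form`), with `sin` the default because its inversion of
the numerically integrated elastica stays within 2% of the true modulus up
to 10°, degrading monotonically beyond — that validity curve is part of the
test suite.  A warning is attached above 10°.

**Weight force.** `F_G = rho g V` with `V` the raised-liquid volume.  At
experiment scale this is a ≤1% correction and is reported, not subtracted.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| surface tension sigma | 0.07275 | N/m | water at ~22 °C |
| density rho | 998 | kg/m³ | water at ~22 °C |
| gravity g | 9.81 | m/s² | — |
| derivative stencil | 3-point | — | exact for quadratic E(y) |
| fit residuals (pipeline) | orthogonal | — | slender menisci have near-vertical flanks; vertical residuals are slope-amplified there.  `vertical` (with analytic Jacobian) remains the bare `fit_profile` default |
| area quadrature epsabs | 1e-12 at mm scale | m² | scaled by `(max(a,b)/1 mm)²` so µm-scale results keep relative accuracy |
| volume quadrature epsabs | 1e-15 at mm scale | m³ | scaled by the cube of size, same reason |
| Monte-Carlo error draws | 200 | — | ~5% relative precision on the error estimate itself |
| bending validity bound | 10 | deg | 2% inversion accuracy limit |

## Image analysis

Backlit frames are thresholded (Otsu by default, with a bimodality guard
and a fixed-threshold escape), and every edge is refined to subpixel by
linear interpolation of the threshold crossing — which can never move a
point more than one pixel from its integer detection.  The flat far-field
surface gives the baseline; the silhouette width at and above the
fiber–liquid junction gives `r_tip`; meniscus flanks are sampled per image
row (half-width left/right edges), which stays well-conditioned for steep
flanks.  The tension-mode tip height is taken from the fitted meniscus apex
`y(r_tip)` — the tip *is* the attachment point, and the fit averages
hundreds of edge points, so this is far more precise than tracking the
featureless fiber.  The relaxed (post-snap-off) tip is the subpixel bottom
edge of the free fiber.  Template tracking by normalized cross-correlation
with parabolic peak interpolation is provided for scenes with texture.  A
manual-annotation CSV (frame_index, x_px, y_px, label ∈ {flank, tip,
baseline, fiber}) mirrors a fully visual workflow and feeds the same
analysis chain.

The snap-off frame is defined as the last frame whose silhouette connects
the liquid to the fiber (some image column is dark from top to bottom).

Baseline height and the profile offset `c` are exactly degenerate in a
joint fit (both are vertical offsets), so the baseline is measured
independently from the far field, points are normalized to it, and the fit
estimates `(a, b, c, axis_x)` only.

## Error model

Two error bars accompany every quantity, in the convention "value ±
statistical ± systematic":

* **Statistical** — per measurement, the fit's rms residual propagated to
  first order through the parameter covariance, the energy gradient and the
  finite difference; across replicates, the standard error of the mean.
* **Systematic** — the ±0.5 px localization limit of the camera, propagated
  through the full chain by first-order sensitivities (point → fitted
  parameters via the least-squares Jacobian; parameters → energy and tip
  height; energies/heights → force, elongation, stiffness, modulus).  Two
  numbers are reported: a deterministic **worst case**, in which
  quantization acts coherently along each contiguous edge feature (each
  flank, the junction width, the baseline, each tip) with adversarial signs
  across features and frames — a guaranteed first-order bound, and the
  headline systematic error; and a **Monte-Carlo** value (n = 200, seeded)
  with every coordinate drawn independently and uniformly in ±0.5 px.
  Per-point adversarial signs were rejected as a worst case: no physical
  scene can quantize neighbouring crossings of one smooth blurred edge with
  independent signs, and the resulting bound (several times the measurand)
  carries no information.  Both numbers scale linearly with the pixel size
  and vanish in the perfect-camera limit.  Sequences carrying only visually
  assessed parameters (no point-level fits) fall back to ±0.5 px on each of
  a, b, c and r_tip directly.
* Pooled systematic errors over replicates are the mean of per-measurement
  systematics — a resolution-limited error does not shrink with √n.

## The synthetic generator

The generator is the package's ground truth and defines its study
conditions.  It emulates the published experiment scale: a ~20 µm tip whose
snap-off pull force sits at the contact-line capillary scale
`2 pi sigma r_tip` (~15–25 µN over the pull), a 2 N/m Hookean structure
(elongations of 8–15 µm), a 768 × 576 8-bit camera at 0.6 µm/px with 1 px
Gaussian optical blur and 3 gray-level noise, and a 120 µm/s constant pull.
The meniscus family grows in height and spreads slightly in outer radius
between frames, with analytic energy and force from elementary closed forms
of the ellipse-zone area — an oracle independent of the quadrature used by
the analysis, so the round-trip tests do not depend on the family chosen.
Frames are rasterized at 4× supersampling (area-weighted edges), then
blurred, noised and quantized; all randomness flows from one seed and
renders are byte-reproducible.

The *experiment-scale geometry sampler* used for the weight-force study
draws tip radii in 10–50 µm and meniscus heights in 0.3–2 mm, then solves
the outer radius so the analytic pull force lies 5–50% above
`2 pi sigma r_tip` — the detachment force scale, and the exact lower bound
of the elliptic family as `a → r_tip`.  This is what near-snap-off menisci
look like: tall ones are slender.  Sampling wide, tall elliptic domes
instead would store ~1 mm³ of liquid and violate the negligible-weight
regime that the real experiment demonstrably operates in.

**What passing tests do not show.**  The renderer draws the elliptic model
itself, so round-trip recovery validates the extraction/fitting/energy
chain, not the adequacy of the elliptic approximation to real
Young–Laplace menisci.  It also omits illumination gradients, lens
distortion, depth-of-field asymmetry, evaporation, contact-line pinning
hysteresis and vibration; on real data these enter the systematic budget
and the elliptic-fit residual should be inspected.  Dynamic (viscous)
effects at 120 µm/s are assumed negligible, as in the quasi-static model.

## Numerical choices and degenerate inputs

* Surface-of-revolution quadrature uses the substitution `x = a sin(theta)`,
  removing the vertical-tangent singularity at the outer radius; generic
  meridians get a plain adaptive rule (`revolution_area/_volume`).
* The profile fit runs bounded trust-region least squares with an analytic
  Jacobian (vertical residuals) or Newton-projected signed orthogonal
  distances; the meridian is analytically continued beyond `|x| = a` so
  points that fall outside the current ellipse iterate keep a gradient.
* Collinear points, fewer than 8 points, or a single flank without an axis
  estimate raise a degeneracy error; a single flank is detected by the
  strong monotone correlation between x and y that one branch of the
  ellipse exhibits and two mirrored flanks do not.
* Non-monotone energy samples beyond noise attach a warning to the force;
  zero elongation makes the stiffness unresolvable (error, not infinity).
* Tie-break: if several frames qualify, the snap-off frame is the *last*
  connected one.

## Validation problem sizes

The shipped validation runs 20 seeded rendered sequences of 8 pull frames
plus one relaxed frame at full camera resolution, 200 sampled weight-force
geometries, 5 bending angles between 1° and 10°, and 200-draw Monte-Carlo
error propagation — sizes at which the end-to-end suite completes in well
under a minute while estimating 90%-coverage fractions with ±7%
(binomial) resolution.

## Known limitations

* The elliptic profile is an approximation; strongly non-elliptic menisci
  (very large Bond number, near-zero contact radius) will show inflated fit
  residuals, and the reported errors do not include model error.
* The energetic force estimator needs at least two (preferably three)
  analyzable frames before snap-off; single-frame experiments cannot be
  evaluated.
* Bending mode trusts the user-supplied fiber length and diameter; their
  uncertainties are not propagated (d enters as the fourth power).
* The imaging heuristics assume the single-fiber CAT scene: one structure,
  one meniscus, a visible flat far field on at least one side.
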