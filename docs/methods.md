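# Methods

## The geometric model

The synthetic wood is a Cartesian slab with coordinates (r, t, z) =
(radial, tangential, axial), r increasing pith → bark.  Stem curvature is
ignored; for sectors up to a few centimetres wide at breast height the
curvature of the rings across the sector is well below the section
thickness, so the error is negligible.  The radial axis is partitioned
into `n_rings` annual rings with lognormal widths (mean 1.047 mm, CV 0.2
by default — a typical mature pine increment core); the outer
`latewood_fraction` (default 0.3) of each ring is latewood.

Rays are modelled as radially oriented fusiform **uniseriate sheets**.  At
every radius inside its span, ray *i* occupies the lens

    |t − t_i| ≤ s(r) · (w_i / 2) · (1 − u²)^p ,   u = 2 (z − z_i) / h_i ,  |u| ≤ 1

with maximum tangential width `w_i` (default 25 µm), height `h_i`
(lognormal, mean 180 µm, CV 0.3), and lens exponent `p ≥ 0` (default 1, a
pointed spindle; `p = 0` is a rectangular sheet).  The height and width
defaults are stated placeholders — the literature gives ranges, not
distributions, for this material — and every recovery experiment
calibrates the quantity it measures, so conclusions do not hinge on them.
The lens cross-area is `w·h·B(p)` with `B(p) = √π Γ(p+1) / (2 Γ(p+3/2))`
(`B(1) = 2/3`).  An optional linear height increase with radius
(`ray_height_growth`, µm/mm, default 0) reflects the pith→bark increase in
ray height; it is off by default because no parameterization is
established.

`s(r)` is a piecewise-constant width modulation shared by all rays: within
latewood bands it is multiplied by `latewood_perpar_multiplier` (default
6.18/5.77 ≈ 1.071, slightly larger parenchyma near the ring border), and
each ring is multiplied by a lognormal **year factor** with mean 1 and CV
`interannual_cv` (default 0.12, the observed inter-annual CV of annual
ray fraction).

**Placement.** Ray centres form a point process in the (t, z) plane,
padded beyond the sector so that sections anywhere inside see a
stationary ray field.  The default is a binomial process (fixed count
`round(density × area)`, uniform positions) with **hard-core thinning**:
rays whose axial ranges overlap keep a tangential centre distance of at
least their half-widths plus one mean ray width, so uniseriate rays never
merge — as in real tangential views.  A Poisson-count mode and a
no-thinning mode exist (`poisson_counts`, `hard_core`); the coverage
calibrations below assume independent placement and therefore switch the
hard core off.

**Persistence and turnover.** By default rays span the whole radial
extent (rays extend to keep their cambial connection).  Optionally, rays
truly end with per-ring probability `termination_probability`, at a
uniform radius within the terminal ring, and new rays initiate at
`initiation_density` per mm² of tangential plane per ring, with a
latewood:earlywood initiation-rate ratio `latewood_initiation_multiplier`
(per mm of radial growth).  Terminating uniformly *within* the ring makes
the standing density exactly stationary when the initiation rate equals
`density × termination_probability`; terminating only at ring borders
would create a saw-tooth density profile within rings and bias
early/latewood comparisons.  A third mode (`initiation_segment`) makes
initiated rays short transient radial segments, used to emulate the
artifact-inflated initiation counts of real sections.

## Virtual sectioning

A section is a slab of thickness τ (default 15 µm, a standard permanent
thin section) normal to one axis.  Because thin sections are transparent,
a pixel is labelled with a ray iff the line through the pixel centre along
the slab normal meets the ray **anywhere** within the thickness — a binary
maximum projection, not an opacity-weighted one.  Consequences:

* **tangential** sections (normal r) of persistent rays show a single
  lens outline — the areal fraction is an unbiased estimate of ray volume
  (the classical areal = volume fraction principle), and with hard-core
  placement the estimate is exact up to raster noise;
* **cross** sections (normal z) show each ray at its widest within the
  slab: expected coverage per unit width is λ = ρ·w·(B(p)·E[h] + τ)
  instead of ρ·w·B·E[h] — a mild overestimate via the tapering ray tips;
* **radial** sections (normal t) show the full radial-longitudinal
  silhouette of any grazed ray: coverage ρ·E[h]·(B(p)·w + τ), a gross
  overestimate since τ is comparable to w.  This reproduces the observed
  plane ordering radial ≫ cross > tangential.

**Misalignment** tilts the slab: cross-sections about the tangential axis
(the slab centre drifts axially with radius), radial sections about the
axial axis, tangential sections about the radial axis.  A tilted
cross-section makes rays drift in and out of the slab along the radius,
creating matched pairs of spurious initiating and "ending" rays; at 0°
tilt and zero turnover, no ray ever disappears.

**Raster.** Pixels are 0-based with half-open footprints; a pixel is
"ray" iff its centre lies inside the projected outline, which makes areal
fractions unbiased for uniformly positioned rays.  Default resolution is
2 µm/px (≥ 12 px across a 25 µm ray; a 4 × 4 mm section is 4 Mpx).
Overlapping projections resolve to the lowest ray id, with per-pixel
multiplicity recorded.  Exact vector outlines (`projected_outline`)
back the geometric unit tests.

## Ray metrics

Outlines are extracted per label id (area, axis-aligned extents,
centroid).  Ray width follows the measurement convention width =
area/height on tangential outlines (area/length on the other planes).
Counting conventions:

* outlines touching any image edge are excluded from **dimension**
  statistics (their extents are censored) but count toward PERPAR, a pure
  area fraction;
* initiating/disappearing counts use an unbiased counting frame: the left
  tangential edge is a forbidden line (touching it excludes the outline;
  the right edge does not), so the expectation per mm of width is exact
  despite clipping; ends censored by the top/bottom image edge are never
  counted;
* a ray **initiates** in a ring if its inner radial end lies more than one
  pixel beyond the ring's inner border (the tolerance absorbs raster
  jitter), and is assigned to earlywood/latewood by the position of that
  end, not its centroid; disappearing rays are the mirror rule at the
  outer border;
* standardized NEWRAY is the count divided by the measured tangential
  width in mm.  The source material reports per-mm-width standardization
  even though the zones differ in radial depth, not width; the per-mm-width
  form is implemented as stated.

## Accuracy analysis

Per-window PERPAR values (axis-aligned windows placed uniformly at
random, overlaps allowed, fully inside the image; cross-sections use
full-height strips of given width) are pooled as exchangeable values.
"Measuring s times the surface" is simulated by drawing s values with
replacement and averaging — the mean, not the sum, keeps estimates on the
PERPAR scale, since PERPAR is intensive.  The CV of the bootstrap
estimates (sample sd over mean, n−1 denominator) gives the per-sample
precision, and

    CI95 = 2 · CV · n^(−1/2)   (% of the mean)

converts it to a relative 95 % confidence interval for n samples
(CI95 ≈ 2·SE, SE = SD/√n, SD = CV·mean).  The planner returns the
smallest integer n meeting a target CI95 (ceiling — conservative for
design).  No block bootstrap is attempted: windows are treated as
exchangeable, matching the pooling design.  This stage is exposed
statsmodels-style as `PerparAccuracy` / `PerparAccuracyResults` because it
is the one genuinely statistical model-fit in the pipeline; the
simulation stages keep a functional pipeline shape.

## Statistics

Mean sensitivity MS = 100 · mean |2(xₜ − xₜ₋₁)/(xₜ + xₜ₋₁)| (the standard
dendrochronology form, fixing the otherwise ambiguous denominator of an
"average percentage change"); CV = sd(n−1)/mean.  Pearson r with two-sided
p from the t distribution (n−2 df); paired t tests (pairing by tree×ring,
the natural repeated-measures structure; Welch two-sample as a fallback
flag); OLS allometry with R² = 1 − SSres/SStot.  Identical paired samples
return t = 0, p = 1; constant non-zero differences raise (t would be
infinite).  No multiple-testing correction is applied; significance
markers use the conventional 0.001/0.01/0.05/0.1 thresholds.

## Calibrations

All calibrations are closed-form inversions, so reported means can serve
as generator ground truth:

* **volume fraction**: density = VF / (w̄ · E[h] · B(p)), with w̄ the
  zone-averaged effective width — linear, hence idempotent; targets above
  50 % are rejected (non-overlapping placement infeasible);
* **cross-section zone means**: independent placement makes per-pixel
  coverage the 1D Boolean-model value 1 − e^(−λ) with
  λ = ρ·w·(B·E[h] + τ); the early/late targets are inverted for density
  and the latewood width multiplier (and the steady-state initiation rate
  when turnover is on);
* **initiating rays**: expected visible initiations per mm of width are
  κ_zone · (E[h] + τ); zone targets are inverted for the total initiation
  density and the per-mm-radial latewood rate ratio.  Detection of every
  visible ray additionally wants a rectangular profile (p = 0): a pointed
  lens grazing the slab edge projects a sub-pixel sliver that the raster
  misses (~4 % of visible rays at p = 1, 2 µm/px);
* **mean sensitivity**: for i.i.d. lognormal year factors the relative
  annual step equals |2·tanh(Y/2)| with Y ~ N(0, 2σ²); E MS is evaluated
  by adaptive quadrature (the |·| kink defeats Gauss-Hermite at the 0.4 %
  level) and inverted for σ.  MS ≈ 10.8 % corresponds to a year-factor CV
  of ≈ 0.096.  Note the i.i.d. model cannot match an annual CV of 0.12
  and an MS of 10.8 % simultaneously (i.i.d. implies MS ≈ 1.128 · CV);
  real series are autocorrelated.  The default config carries the annual
  CV; the MS experiment derives its own σ from the MS target.

## Recovery experiments and problem sizes

`raypar.experiments` fixes the study-scale designs (also used by
`scripts/acceptance.py`):

* *tangential recovery*: 20 independent 4 × 4 mm sections, 15 µm, 2 µm/px,
  random offsets; inter-annual modulation off, to isolate sectioning bias
  from temporal variability.  Expected recovery ≈ exact; observed
  Monte-Carlo sd ≈ 0.2 % abs per section.
* *zone recovery*: 40 cores × 20 rings of 6.69 mm width (the average
  measured cross-sectional width of the reference material) with turnover
  q = 0.25.  Turnover matters for precision, not bias: with fully
  persistent rays all 20 rings of a core share one streak sample, and the
  40-core Monte-Carlo error would exceed the ±5 % recovery band; real
  cores demonstrably renew rays ring by ring.
* *initiation recovery*: same core design at 2 mm width (counts per mm
  are intensive and dense, so narrow sections already give < 1 % standard
  error); rays as transient 0.12 mm segments with p = 0 and per-zone
  intensities calibrated to the target counts.  The reported initiation
  rates are far above what persistent sheets could sustain jointly with a
  ~6 % areal fraction — transiently appearing rays, which the segment mode
  emulates, are the only geometry consistent with both.  Residual
  occlusion loss is ~1 %.
* *mean sensitivity*: 40 series × 20 rings; MS is computed on the model's
  annual ray-volume series (linear in the year factor).  An imaged series
  would add window-sampling noise, which is a property of the measured
  surface, not of the inter-annual parameter being recovered.

## What the generator does and does not emulate

Emulated: uniseriate fusiform ray geometry and its plane-dependent
projection artifacts; ring structure with zone contrasts in ray width and
initiation; inter-annual modulation; spatial non-merging of rays; ray
turnover.  Not emulated: individual parenchyma cells, marginal ray
tracheids and pits; resin ducts (excluded from ray measurements); ray
shape irregularity and curvature; staining contrast, focus blur, section
compression or tearing; segmentation error of real image analysis;
spatial autocorrelation of ray density beyond the hard core; biseriate or
multiseriate rays.  Passing recovery tests therefore demonstrates that
the *measurement pipeline* is unbiased and correctly calibrated for this
geometry — not that real micrograph segmentation is error-free.

## Numerical choices and degenerate inputs

Lognormal ray heights are resampled above exp(µ + 5σ) so placement
padding can bound the visibility window (truncation error < 10⁻⁵
relative).  Zero-thickness slabs are honoured exactly (a plane at a span
endpoint still cuts the ray).  Degenerate width-modulation windows on a
segment edge fall back to the containing segment.  Zero-variance inputs
raise rather than return silent zeros (CV, Pearson, OLS on constant x),
except identical paired samples (t = 0, p = 1, see above).  Hard-core
placement retries 200 positions before declaring the density infeasible.
Exact ray volumes clip boundary rays by 64-node Gauss-Legendre
quadrature; overlapping ray clusters fall back to Monte-Carlo union
volumes (10⁵ points per cluster).  All randomness flows from one integer
seed through named CRC-derived substreams; repeated runs are
bit-identical, including PNG bytes and manifest hashes.

## Known limitations

* The Cartesian sector has no circumferential growth, so strict
  stationarity of ray density pith→bark is imposed by the turnover
  balance rather than emerging from fan-out geometry.
* The Boolean coverage inversion assumes independent placement; with the
  hard core on, measured cross-sectional coverage sits up to ~3 %
  (relative) above the 1 − e^(−λ) value.
* Per-ring year factors modulate ray width only; real inter-annual
  variation likely mixes width, density and cell-size effects.
* The transient-segment initiation mode reproduces measured initiation
  counts, not the biology of ray lineage dynamics.
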