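# Methods

## The motion surrogate

`biokin` describes segmental spine motion purely geometrically — no forces,
no constitutive biomechanics.  Each motion segment (two adjacent vertebrae
and their disc) is reduced to a **biokinemetric triangle** in the sagittal
plane: the baseline runs along the lower vertebra's upper endplate from its
anterior (leading) edge (landmark 1) to the ascending facet (landmark 2);
the apex (landmark 3) is the posterior edge of the upper vertebra at the
roof of the neuroforamen.  After rigid registration into the segment frame
(landmark 1 at the origin, landmark 2 on the positive first axis) the
baseline is fixed across all frames of an exam, so only the triangle's
height — and hence its unsigned area S — changes with segmental pose.  S is
the per-segment motion measure; the shoelace formula computes it, and a
rigid-transform property guarantees it is independent of patient positioning
in the image.

Coordinates are calibrated from pixels to millimetres with a single scalar
scale from a gauged X-ray ball of known diameter.  Projective magnification
gradients across the field are ignored — one ball yields one scale.

## Motion curves and the percentage-of-movement axis

A **RoM curve** plots S against the percentage of the whole section's
inclination-to-reclination sweep.  The global sweep angle is measured
between the most caudal endplate baseline and the most cranial *available*
baseline (the lower vertebra of the topmost segment — the topmost segment's
own upper endplate is not part of the landmark schema).  The inclination
pose maps to 0 %, reclination to 100 %; intermediate frames beyond the
endpoint arc are clamped with a warning rather than rejected.

Sparse clinical 3-pose exams (inclination / neutral / reclination) are
densified with a shape-preserving monotone cubic (PCHIP) interpolant: it
passes through every knot and cannot overshoot the local knot range, which
matters because S is a physical quantity.  Dense videofluoroscopic exams
bypass interpolation.  Motion curves always carry their source
(`measured`, `interpolated`, `virtual`).

A **motion surface** stacks one segment's curves acquired at several phase
offsets; the locus of strongest curvature of the neutral-offset curve
(largest |second derivative| by central differences) is reported because
adjacent-segment motion initiation concentrates there.  Flat or linear
curves have no such locus and are flagged indeterminate.

## Signatures and reproducibility

Each segment is condensed to the dimensionless ratio **dS / S_max** (area
range over the sweep divided by the maximal area): scale-invariant, so
patient size and radiographic magnification cancel.  A section is the
cranial-to-caudal series of these numbers.  Series are compared by
Euclidean distance — chosen because it is the metric implied by the
Gaussian identification machinery below.

Reproducibility is framed as subject identification: every subject is
measured twice, each subject is one class, the class mean is the subject's
mean ratio vector, and a shared diagonal covariance is estimated from
within-subject session differences (Var = E[(x1-x2)^2]/2 per level; exact
duplicates are ridge-regularized and flagged).  The **Bayes error** of the
equiprobable multi-class decision rule is estimated by seeded Monte-Carlo
integration (default 1e5 draws; the Monte-Carlo SE is reported), and a
leave-one-out 1-nearest-neighbour error is reported alongside as a
distribution-free check.  A low error means repeated exams attach to
individuals like a fingerprint.  The Monte-Carlo engine reproduces the
closed form for two univariate Gaussians with mean gap 2*sigma,
Phi(-1) = 0.1587, within its sampling error.

## Worst/best segment detection and disc-height estimation

Patient curves are compared level-by-level against a **reference
surrogate** of healthy, normalized per-level curves (plus neutral disc
heights and level size ratios; distal discs are larger than proximal ones,
so size ratios are nondecreasing caudally).  The deviation score is the RMS
difference of self-normalized curves on a common 101-point fraction grid.
The *worst* segment maximizes deviation (ties break to the most caudal
level, where degeneration prevails, and are flagged).  The *best* (donor)
segment maximizes `w_h * (height / reference height) - w_c * deviation`
with default weights 0.5/0.5, excluding the worst level so donor and
recipient can never coincide.

Two estimator details, both confined to the comparison layer (motion curves
themselves are never altered):

* **Dense-curve regularization.**  Curves with >= 10 knots are resampled
  through a smoothing spline whose smoothing parameter is the
  second-difference noise estimate of the knot values (sigma^2 ~
  mean(d2^2)/6).  A noise-free curve therefore passes through its knots
  unchanged, while annotation jitter is suppressed before the RMS
  comparison.
* **Rank-based disc-height regression.**  The neutral disc height enters
  the triangle as the apex's motion-free clearance, h = 2*S0/baseline.  S0
  is estimated as the intercept of regressing the measured areas on the
  reference's normalized motion profile — pairing samples by sweep rank
  (both exam frames and the stored reference sample the sweep uniformly)
  rather than by the measured percentage axis.  The percentage axis is
  normalized by the two noisy endpoint angles, which injects a shared scale
  error that would dominate the intercept; rank pairing removes it.  Without
  a reference the raw minimum 2*S_min/baseline is used.

## Implant planning

*Virtual substitution* copies the best segment's self-normalized curve into
the worst level, rescaled by the size-ratio quotient, so the signature ratio
transfers unchanged.  The *height recommendation* carries the best level's
preserved height over with the same quotient and caps it at the reference
neutral height of the worst level (anti-overcorrection); a result at or
below the current height raises a no-change flag.  Recommendations map to
the manufacturer grid by nearest height, ties to the smaller (less
distraction), with a 0.05 mm exactness margin.

A device is reduced to its height grid and a single **mobility factor** in
[0, 1] — the fraction of the healthy segmental range it preserves (0 =
rigid fusion cage, forced for cages).  *Post-op prediction* is this
package's surrogate for intersegmental communication: the implanted level's
range becomes `mobility_factor x healthy reference range` (reference ratio
at patient scale), and the removed range is redistributed to the immediate
neighbours in proportion to their current ranges, conserving the section's
total range exactly.  Curves are rescaled about their own S_max so maxima
are preserved.  The rule is deliberately minimal; it is the package's model,
not a biomechanical claim, and it yields three testable properties:
conservation, monotonicity of adjacent dRoM in the mobility factor (for a
hypermobile target), and idempotence.

**dRoM** — |change of a level's area range between two exams| — is the
adjacent-segment effect measure.  Outcome association uses Pearson
correlation between per-subject mean adjacent dRoM and *relief* (the
negated outcome delta), with a two-sided seeded permutation p-value (1e4
permutations), so a deleterious implant effect appears as a negative
correlation.

## The synthetic spine generator

No patient radiographs ship with the package; the generator is the test
bed.  It emulates calibrated sagittal landmark trajectories of a cervical
(C2-C7) or lumbar (L1-S1) section over an inclination -> neutral ->
reclination sweep:

* All segments share one logistic motion characteristic over the sweep,
  each shifted by its own phase offset (every segment sits at a different
  point of its individual movement sequence), normalized so each segment
  traverses exactly its configured excursion between the endpoints.
* **Angular kinematics are decoupled from area kinematics.**  Segment arc
  shares are fixed weights of the global arc (they always sum to the
  configured arc), while the triangle apex rides at
  `disc height + mobility x amplitude x sigma(t)` above the baseline.
  Degeneration (height loss, hypo-/hypermobility) and devices act on the
  area surrogate without breaking the angular sweep; this keeps arc-sum and
  motion-conservation invariants exact and makes truth values closed-form.
* Landmark noise is isotropic Gaussian on pixel coordinates, calibrated per
  level so the induced SD of the triangle area equals
  `noise_sd_fraction x S_max` (the first-order variance of the shoelace
  area under iid vertex noise).  Noise enters upstream, as in real
  annotation.  A per-frame rigid jitter of the whole section exercises
  registration and cancels exactly in every measurement.
* Device application mirrors the planner's redistribution rule, so cohort
  truths (per-level ranges, adjacent dRoM) are closed-form.
* Outcome scores are generated on the NDI fraction scale (pre ~ 0.38,
  worsening = slope x mean adjacent dRoM + noise; defaults slope 0.003 per
  mm^2, noise SD 0.01).  These are plausible fixture magnitudes, not
  clinical predictions.

Key defaults (cervical / lumbar): global arc 60 deg / 50 deg; disc heights
5.5 mm / 10 mm at the cranial end, growing caudally with size ratios
1.00-1.12 / 1.00-1.20; baseline lengths 15 mm / 35 mm scaled the same way;
level weights near-uniform; phase offsets -10..+10 %; amplitude fraction
0.8 of disc height (healthy dS/S_max ~ 0.44); calibration ball 30 mm at
150 px (0.2 mm/px); annotation noise 5 % of S_max.

What the generator does *not* emulate: out-of-plane motion and projective
distortion, correlated annotation errors, irregular sweep velocity,
inter-vertebral shape variation, and real degeneration patterns beyond
height/mobility changes.  Passing the validation experiments therefore
shows the *pipeline* is correct and well-conditioned under realistic noise,
not that the surrogate model is clinically validated.

## Validation experiment design

The experiments in `biokin.experiments` (run by `scripts/acceptance.py` and
the acceptance tests) use these study conditions, chosen from an error
budget before freezing the suite:

* Recovery experiments (worst/best detection, implant height) use dense
  61-frame sweeps — the videofluoroscopic acquisition from which the motion
  model derives — at 5 % annotation noise, 200 replicates.  The degeneration
  pattern is caudal-prevalent: target C5-C6 with mobility halved and 2 mm
  height loss, a pristine donor at C3-C4, mild degeneration elsewhere.
* The identification cohort uses 20 subjects, two 3-pose sessions each,
  0.3 % session noise against between-subject mobility variation (SD 0.2),
  which realizes a between/within separation >= 10 SDs.
* Conservation/monotonicity runs model an unstable hypermobile target
  (mobility 1.3-1.9), the fusion indication; with a hypomobile target a
  fully mobile prosthesis would *restore* motion and |post - pre| of the
  neighbours would no longer be monotone in the mobility factor.
* The outcome study uses 100 cohorts of 30 subjects, cage implantation at
  C5-C6, a repeated calibrated-radiograph protocol at 1 % annotation noise
  and 5 frames, and measures adjacent dRoM through the full landmark
  pipeline.  The null arm (slope 0) uses 50-subject cohorts.  Note that the
  sampling SD of a null Pearson r is ~ 1/sqrt(n-1) (~0.14 at n = 50), so
  the fraction of null cohorts with |r| < 0.2 is bounded near 0.84 by the
  r distribution itself, independent of the pipeline.

## Numerical choices and degenerate inputs

* Areas are unsigned; collinear landmarks yield zero area with a degeneracy
  flag/warning, not an error.  Coincident baseline landmarks are an error.
* Duplicate percentage values in one exam are averaged; fraction axes are
  strictly increasing thereafter.
* Bayes machinery: ridge floor 1e-12 x max variance on the shared diagonal
  covariance; Monte-Carlo draws chunked at 2e4 to bound memory.
* Ties in worst detection break caudally (flagged); device grid ties break
  to the smaller height; exact-availability margin 0.05 mm.
* Permutation p-values use the add-one estimator (1 + #extreme)/(B + 1).
* Seeds: every stochastic routine takes an explicit seed or Generator;
  per-exam streams derive from (config seed, CRC32 of subject and session
  ids), so any cohort is bit-reproducible.

## Known limitations

* Single-plane sagittal analysis; coronal triangles and 3-D reconstruction
  are out of scope, as is landmark detection from images.
* The redistribution rule is a stated surrogate for intersegmental
  communication; it conserves range by construction and is swappable, but
  it is not derived from mechanics.
* Conventional angle-based ROM for the topmost segment needs an explicitly
  supplied upper endplate; the pipeline reports it as missing otherwise.
* The disc-height rank regression assumes exams sample the sweep roughly
  uniformly (true for steady functional sweeps and for the symmetric
  3-pose exam); strongly non-uniform acquisition would bias it toward the
  raw-minimum estimate's behaviour.
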