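# Methods

This note documents the models, conventions and design choices behind
`mibgtools`: what each stage assumes, which knobs matter, what the phantom
generator does and does not emulate, and the numerical conventions used.

## Imaging model and geometry conventions

**Planar metrics.** The H/M ratio is a pure ratio of ROI means of
counts/pixel; no smoothing, scatter or attenuation handling is applied.
The heart ROI is supplied as a mask (visual ROI placement on patient data
is not reproducible in software); `auto_heart_roi` (largest connected
component above half the image maximum) is a convenience for phantoms
only.  The mediastinal ROI must tile 1,200 mm² within ±10 % — pixels
rarely tile the standardised area exactly, so the tolerance is explicit
and violations raise.

**Washout rate.** The default form is background-subtracted and not
decay-corrected:
`WR = 100·[(Hₑ−Mₑ) − (Hₗ−Mₗ)]/(Hₑ−Mₑ)`.
Reporting conventions for WR differ between laboratories; the
decay-corrected variant (late means multiplied by `2^(Δt/13.2232 h)`,
Δt from the scans' acquisition offsets, defaults 0.25 h and 4.0 h) is
exposed behind `decay_correct=True` so the choice is always explicit in
results.  Typical uncorrected washout rates in the mid-to-high 20 % range
correspond to corrected values roughly 15 points lower.  A nonpositive
background-subtracted early numerator raises rather than clamps.

**17-segment geometry.**  One convention is stated once and used by both
the analyzer and the phantom generator: the LV long axis runs base → apex;
the apical cap (segment 17) is the most apical 15 % of the axis; the
remaining 85 % splits into three equal basal/mid/apical bands; the
short-axis angle θ is measured from the anterior reference direction and
increases anterior → septal → inferior → lateral (as viewed from the
apex); 60° sectors (basal/mid) and 90° sectors (apical) are centred on
their compass directions.  Wall membership is by count threshold (default:
counts above 50 % of the volume's 99th-percentile count, configurable).
Segment statistics use the mean of the top decile of wall-voxel counts —
a radial-maximum-like statistic robust to wall-thickness and
partial-volume variation.  Published deformable contour-finding methods
(elastic surface models) are deliberately out of scope; a fixed polar
sampler is sufficient for consistent per-segment summaries and is exactly
invertible on phantoms.  When late images may contain near-absent uptake,
the wall contour should be (and in `run_study` is) derived from the early
volume and reused, as a count threshold on the late image would drop
defective segments.

**Normalisation.** Segmental uptake is expressed as percent of the
hottest segment at the same time point (`max = 100` exactly).  Because
each time point is self-normalised, segmental washout (early − late) can
be negative when a segment retains tracer better than the hottest one;
this is expected behaviour, not an error.

## Scoring and the deficit rule

Late uptake is discretised at 70/50/30/10 % of the maximal segment
(boundaries belong to the upper band).  These cutoffs follow the
conventional five-point defect scale used in visual semiquantitative
reads; since visual calibration is not standardised, they are
configurable and every result records the thresholds used.

The deficit rule is interpreted as a *qualification filter*: a segment's
score counts toward the SDS ≥ 3 deficit threshold if the score is ≥ 3
(severe segments need no neighbour) or if the score is 1–2 and at least
one adjacent segment is abnormal (score ≥ 1); the reported SDS itself is
always the plain 17-segment sum.  An alternative global reading (deficit
⇔ SDS ≥ 3 and an adjacency condition holds somewhere) is available as
`mode="global"` for sensitivity analysis; on two-isolated-mild-segment
patterns the two modes agree, and both reject them.  "Abnormal" for the
neighbour test means score ≥ 1 (the weakest, most inclusive reading).
The rule is monotone: raising any score can never abolish a deficit —
verified exhaustively on all ≤ 2-segment patterns and on 10⁵ random
patterns against an independently coded interpreter.

Adjacency is a fixed graph: the three sector rings (basal, mid, apical),
basal–mid spokes between equal sectors, mid–apical edges wherever the 60°
and 90° sector spans overlap with nonzero measure (sectors touching at a
single boundary point, e.g. mid-inferior/apical-septal, are *not*
adjacent), and the apex adjacent to all four apical segments.

## Phantom generator

The LV is a half-ellipsoid shell (closed apex, open base): outer
semi-axes default (30, 30, 50) mm, wall 10 mm, voxelised at 2.5 mm on a
48³ grid.  Each AHA segment has a uniform tracer concentration
(counts/voxel expectation) at each time point; outside the wall a uniform
background (default 40) fills the grid.  Defaults put ~800 expected
counts/voxel in the wall early and 0.73 of that late — count densities
and a global washout typical of 370 MBq ¹²³I-mIBG studies.  Poisson noise
is applied voxel-wise to expectations once; planar images are sums of the
(noisy) volume along the anterior–posterior axis, plus a mediastinal band
(concentration × grid depth per pixel, noise applied at the planar level
for the band only), so noise is never applied twice.  Ground-truth
profiles come from the activity field directly (with uniform per-segment
concentration the top-decile mean equals the concentration), never from
sampled counts.  All randomness flows from the spec's single seed;
identical specs give bit-identical studies.

What the phantom does *not* emulate: attenuation, scatter, collimator
blur, cardiac/respiratory motion, ECG gating, anatomic background
structures (liver, lung), wall-thickness variation, and reader
variability.  Passing tests therefore demonstrate correctness of the
quantification chain and its noise robustness at clinical count levels —
not performance on real patient images.

Synthetic cohorts draw deficit and relapse labels independently per
patient (defect ~ Bernoulli(p_defect), relapse ~ Bernoulli conditioned on
defect); defaults (n = 16, 62.5 % post-PVI deficit prevalence, relapse
probabilities 0.4 / 0.167) mirror the structure of the clinical series
the package models.  Demographics are decorative and carry no signal.

In the end-to-end simulation (`run_study`), deficits are planted as a
contiguous inferolateral patch (segments 5, 11, 16 — where the clinical
series localised new defects) with late uptake dropped into the severe
band; pre-PVI deficit prevalence defaults to 25 % and deficits persist
after PVI, with new ones raising prevalence to 62.5 %.

## Statistics

Exact nonparametric tests are used wherever enumeration is feasible:

- **Wilcoxon signed-rank** — zero differences are dropped (and counted);
  absolute differences receive midranks; for ≤ 20 nonzero differences the
  null distribution of W⁺ is enumerated exactly over all 2ⁿ sign vectors
  via a convolution over doubled midranks (tie-aware); beyond that, a
  normal approximation with tie-corrected variance
  `n(n+1)(2n+1)/24 − Σ(t³−t)/48` (no continuity correction).
- **Mann–Whitney U** — exact enumeration over all C(n, n_a) group
  assignments whenever that count is ≤ 200,000 (this covers everything up
  to and beyond 8 + 8 = 12,870 assignments); otherwise the tie-corrected
  normal approximation.  The threshold is set by enumeration cost, not
  sample size, so every cohort-scale comparison in this package is exact.
- Two-sided p doubles the smaller one-sided tail, capped at 1 — the
  standard convention for discrete exact tests.

Diagnostic metrics are reported both raw and rounded to the nearest
integer percent (the printing convention of the clinical literature);
fields with empty denominators are explicitly undefined (`None`), never
0/0.  Group summaries use the sample SD (n − 1); missing values are
excluded and counted, single-observation groups have undefined SD, and
empty groups raise.

The packaged patient table contains relapse status per patient but no
per-patient deficit status (only group counts were published), so the 2×2
reproduction distributes deficit labels among relapse strata to match the
published counts — the table and all metrics are invariant to which
patients within a stratum carry the label.  Per-patient SDS values were
likewise never published, so the pre/post SDS comparison is covered
structurally (simulator + exact Wilcoxon machinery), not numerically.

## Problem sizes and numerical choices

Default test and acceptance problem sizes: 48³ phantom grids (≈ 4,000
wall voxels, ≥ 200 voxels per segment), 100 noise seeds for the Poisson
recovery check (pass = all 34 segmental uptakes within ±3 pp of truth),
~2.4 × 10⁴ two-segment placements plus 10⁵ random patterns for the
deficit-rule equivalence, and 10⁶ resamples for Monte-Carlo test
verification at n = 16.  Ties in the top-decile statistic are resolved by
`np.partition` (value-based, order-independent); segment boundaries at
exact band edges belong to the more apical band and the
counter-clockwise-following sector, fixed by the floor conventions in
`segment_of`.

## Known limitations

- The polar sampler assumes the LV axis is supplied; no automatic
  reorientation from scanner axes.
- No DICOM import; NIfTI (with an axis-metadata extension) is the native
  interchange format.
- Scoring is deterministic from the profile; inter-reader variability of
  visual scoring is not modelled.
- The mediastinal band placement in phantoms is schematic (a box beyond
  the apex), not anatomical.
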