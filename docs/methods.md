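# Methods

This note documents the models, defaults and numerical choices behind
`pgmorph`, and what the synthetic benchmark does and does not establish
about real micrographs.

## The measurement model

A chloroplast TEM cross-section is treated as a 2D scene: the chloroplast
is a closed region containing bright starch granules and dark PG disks,
surrounded by the vacuole, whose mean grey value serves as the bright
reference for electrodensity.  All areas are pixel counts converted by
(nm/pixel)²; coordinates are pixel-centred, row-major and 0-based, and a
pixel belongs to an object when its centre does.  No sub-pixel boundary
correction is applied: for a disk of radius ≥ 3 px the resulting
circular-equivalent diameter is within 2 pixel-equivalents of truth, which
the round-trip tests enforce.  Mean greys are always computed on the raw
8-bit image, never on a denoised copy, so electrodensity is unbiased by
filtering.

When no physical scale is available a record stays in *scale-free mode*:
only NPG, %PG and nED are derived, since both are ratios in which the
pixel size cancels.

**Image-selection rules.**  Chloroplasts with less than 80% of their
outline visible are excluded (boundary inclusive: exactly 80% is kept),
and at most four chloroplasts are retained per image to avoid
over-representing single biological replicates.  Where a human analyst
would pick "representative" chloroplasts, the package keeps the largest
cross-sections first with a deterministic tie-break on id —
reproducibility is preferred over mimicking judgment.

**Cluster counting.**  Grape-like PG clusters are connected components of
the contact graph (two PGs linked when centre distance ≤ r₁ + r₂ + gap).
The contact gap is not standardised anywhere in the literature we model;
the default is 10 nm and it must stay configurable.  A component of ≥ 2
PGs counts as a cluster by default — a touching pair is already a
biologically meaningful aggregate — with the stricter "more than two"
reading available as `min_size=3`.

## The core/coat partition

Each PG cross-section is split into a neutral-lipid core disk and an
amphipathic lipid/protein coat annulus of fixed thickness t (default
3 nm): core = π·max(r − t, 0)², coat = π·r² − core.  The partition is a 2D
annulus, not a projected 3D shell; the printed fold-changes (×4.6 core,
×2.1 coat, ×2.2 ratio for a 50→100 nm expansion; ratio 3.4 at 50 nm) are
consistent only with the 2D reading, which fixes the interpretation.  The
core radius is clamped at zero below Ø = 2t instead of raising — the
smallest PG observed in real data is 20 nm, so the clamp only guards
synthetic extremes.  Per chloroplast, %Core and %Coat normalise the
*summed* partitions by (CA − starch), and the ratio is the ratio of the
sums, not the mean of per-PG ratios, matching the stated formula.  Two
consequences are used as test invariants: core + coat equals the disk area
exactly for every diameter, and the per-PG ratio is strictly increasing in
Ø with a unit fixed point near 20.5 nm — PGs below it are coat-dominated.

## Effect sizes and summaries

The unit of the meta-analysis is the *case* (article × species × stress
type × treatment level).  Controls: an author flag wins; otherwise the
lowest numeric treatment level; single-level groups without a flag are
dropped with a warning, and equal lowest levels are an error rather than a
guess.  ES = ln(X̄_stress/X̄_control) with means across all chloroplast
cross-sections in an arm (per-image nesting is deliberately ignored).  A
non-positive arm mean (legitimately possible for NPG) yields a null ES
with a logged reason; nulls are excluded from summaries and counted
separately.  Per-stress summaries are unweighted mean ± SE (sd/√n, 0 for a
single case) plus the fraction of negative cases; stress types need
strictly more than `min_studies` (default 10) cases for their own row,
everything pools into an "all stress" row.  Inverse-variance weighting and
publication-bias diagnostics are intentionally out of scope.

## Outlier screening

Tukey fences at 1.5·IQR.  Quartiles use linear interpolation of order
statistics (positions p·(n−1), the default of most numeric software);
Tukey's original hinges are exposed as an option because "Tukey's method"
does not pin down the quartile estimator.  Values are flagged, never
auto-removed — dropping is an explicit opt-in that masks cells to NaN.
Flagging is idempotent: removing flagged values can never push remaining
values outside the original fences.  For large normal samples the flag
rate is ≈ 0.7%; the right-skewed PG attributes flag in the mid-to-high
single digits, which is exactly the skew-sensitivity the screening
exploits.  Screening defaults to per attribute × condition groups; pooling
is available by flag, since the grouping grain used in practice is
ambiguous.

## The synthetic generator

The generator emulates the *marginals* of non-stress PG data, not TEM
optics:

* **Diameters** — log-normal, median 121 nm, log-sd 0.55 (≈ 95% of mass
  between ~40 and ~400 nm), clipped to the observed physical range
  [20, 1500] nm.  The `few_large` population mode adds a heavy-tail
  mixture component (15% weight, log-normal around 600 nm) reaching the
  1500 nm extremes of senescing material; `many_small` doubles counts and
  shrinks diameters.  The data constrain quantiles, not a family; the
  log-normal is a choice.
* **Counts** — negative-binomial shaped, dispersion r = 1, with the mean
  solved numerically so the *mid-distribution* median is 7 (the mid-CDF
  convention keeps the empirical median of a discrete variable centred on
  the target instead of on a CDF = 0.5 boundary).  This puts the upper
  quartile at 14 and the mean near 10.  The implied zero-PG share is
  ≈ 9%; the zero mass is not separately calibrated, so tests do not assert
  it.
* **Greys** — vacuole 200, stroma 120, starch 230, PG 30 (8-bit), giving
  nED = 85, in the high range observed for osmiophilic PGs; additive
  Gaussian noise (default sd 4) on top.
* **Geometry** — one elliptical chloroplast per 512 px scene at
  10 nm/pixel (CA ≈ 8 µm²), 0–2 starch ellipses, PG disks placed uniformly
  inside the outline without interpenetration; a `cluster_fraction`
  (default 0.15) share of disks is attached tangentially to an existing
  disk to create grape-like clusters.  Scenes are strictly 2D: no
  stereological sectioning, membranes, grana or electron-optics texture.

Every scene draws from substreams keyed by (seed, scene index), with the
count drawn by inverse CDF from a dedicated substream.  Two populations
sampled with the same seed therefore share their base randomness, so a
control and a stress case generated with `paired_arms=True` form a
common-random-numbers design in which a diameter multiplier k scales every
diameter exactly and ES(ØPG) = ln k up to measurement error.  Recovery
tests use the paired design (30 images per arm) because it isolates
pipeline fidelity; with independently drawn arms the same ES estimator has
a sampling sd of ≈ 0.08 at that size, which is a property of the study
design, not of the measurement code.  Default studies draw arms
independently, as real studies do.

**What passing tests show.**  Mask-based measurement is exact by
construction, threshold-based segmentation is only exercised on
high-contrast noiseless-to-mildly-noisy scenes, and rendered PGs are ideal
disks.  Success on this benchmark therefore validates the geometry,
bookkeeping and statistics of the pipeline — not automated chloroplast
detection in real, low-contrast published scans, which remains out of
scope.

## Validation fixtures

The reported-vs-measured fixture generator draws, per parameter, reported
values log-uniform over one decade and measured values as slope × reported
with 10% multiplicative noise.  The five default slopes (0.69, 0.83, 0.90,
0.98, 1.30; mean 0.94, SE ≈ 0.11) span the regime observed when
digitised-image measurements are regressed on the numbers the same
articles print in tables.  The slope-vs-1 test is a t-test on
(slope − 1)/SE(slope); the residual sum of the best slope-1 line is also
reported for the least-squares comparison reading.

The effect-size PCA is centred but unscaled by default — the inputs are
already commensurate log-ratios — with unit-variance scaling behind a
flag.  Kendall tau-b (tie-corrected) is used because count attributes tie
often.  Component signs are fixed by making each component's
largest-magnitude loading positive.  Whether the PCA rows should be stress
types (means) or individual cases is not settled; both work via
`es_matrix` on a summary or a per-case pivot, and neither is asserted
as canonical.

## Problem sizes and tolerances

Distribution-level tests use 500 chloroplasts of ground truth (no
rendering); rendered end-to-end tests use 15–60 scenes of 512² px (the
mask-oracle test uses 20 scenes at 192² against brute pixel loops).
Geometry invariants are exhaustive over integer diameters 7–2000 nm at
tolerance 1e-12 relative; stochastic recovery asserts ±0.1 on log effect
sizes; the diameter median check allows 10%, and the discrete NPG median
is checked at its granularity (target inside the empirical 45th–55th
percentile band).
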