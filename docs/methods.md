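# Methods

`capmorph` quantifies the fine structure of skeletal-muscle capillaries from
hand-traced transverse electron-micrograph profiles and reproduces the full
analysis chain of a multi-study morphometric comparison: per-profile
geometric indices, an oblique-section exclusion filter, a two-rater
measurement protocol, per-subject aggregation of peg-socket-junction and
basement-membrane-disruption observations, and a cross-study statistical
battery. Because the underlying biopsy micrographs are not publicly
deposited, the package ships a synthetic-cohort generator with known ground
truth; every claim the test suite makes about the pipeline is a claim about
its behavior on such cohorts.

## Per-profile indices

A capillary profile is described by three nested closed contours — the
blood/endothelium transition (lumen), the abluminal endothelial surface, and
the outer basement-membrane (BM) boundary — plus optional pericyte polygons,
endothelial nucleus polygons, and open polylines for intraluminal
projections. With A an enclosed area and C a boundary length (computed by the
shoelace formula and summed segment lengths, scaled by the per-contour
nm/pixel calibration):

* **Lumen radius** R = 2·A_lumen / C_lumen. Exact for circles; for the
  mildly elliptic profiles that pass the exclusion filter the discretization
  and shape bias is below 1 %.
* **Layer thicknesses.** Two conventions are implemented.
  `consistent` (default) estimates each layer as its ring area divided by the
  mean of its two bounding perimeters:
  EC = 2·(A_abluminal − A_lumen)/(C_abluminal + C_lumen);
  BM = 2·(A_BM − A_abluminal − ΣA_pericyte)/(C_BM + C_abluminal), i.e. the
  pericyte bodies embedded in the BM ring are not counted as BM material.
  `as_printed` evaluates the literal historical formulas, which divide the
  *full* enclosed area of the outer boundary (minus pericyte area for the EC
  layer, minus the lumen area a second time for the BM layer) by a
  denominator that includes the lumen perimeter. The two conventions are
  mutually inconsistent; only `consistent` recovers ground truth on annular
  fixtures (the `as_printed` BM value is negative on a typical annulus), so
  `consistent` is the default and `as_printed` is retained for comparison.
* **Pericyte coverage**: the fraction of the abluminal arc length whose
  radial projection from the lumen centroid meets a pericyte profile.
  Footprints of overlapping pericytes are merged as angular intervals before
  the covered arc length is summed. Radial projection was chosen over
  nearest-point projection because the latter is ill-defined for elongated
  pericytes that wrap around the profile.
* **Nucleus area density**: summed traced nucleus area as a percentage of
  the EC ring area (A_abluminal − A_lumen). Values above 100 % are
  geometrically impossible and mark the profile invalid.
* **Intraluminal surface enlargement**: summed projection length as a
  percentage of the luminal perimeter. The quotient form of the historical
  definition ((C + ΣL)/C ≥ 1) is reported as the excess percentage, matching
  the ~10–17 % magnitudes of the published group values.
* **Aspect ratio**: max/min Feret (caliper) diameter of the abluminal
  contour, computed exactly on the convex hull (maximum vertex-pair distance;
  minimum width perpendicular to a hull edge). Profiles with ratio > 1.2
  (configurable) are flagged as obliquely sectioned and excluded from all
  aggregation, including the frequency denominators. Geometric failures
  (non-nested contours, negative ring areas) flag the profile as
  `invalid_geometry` instead of propagating errors.

## Two-rater protocol

Lumen radius, EC thickness, nucleus area density and surface enlargement are
measured by two raters; BM thickness and pericyte coverage vary negligibly
between trained raters and are taken from the first rater. For each
dual-measured value the relative deviation |v1 − v2| / mean(v1, v2) is
computed — the mean denominator keeps the rule symmetric in the raters —
and pairs deviating by more than 10 % are flagged for repetition; accepted
pairs merge to their mean. Socket counts use the same rule except that pairs
differing by at most one are accepted outright, since percentage rules
degenerate at tiny counts. Software cannot re-measure: a flagged pair is
resolved by a third reading if one is supplied, otherwise the value is left
missing and logged in the discrepancy report. For two independent lognormal
readings with log-scale SD σ the flag rate has the closed form
2·Φ̄(2·atanh(tol/2)/(σ√2)) ≈ 15.7 % at σ = 0.05, tol = 0.10, which the
Monte-Carlo suite verifies.

## Aggregation and statistics

The subject (biopsy) is the unit of analysis: index means are taken over a
biopsy's included profiles, and each peg-socket/disruption observation
becomes the percentage of included profiles on which the structure was seen.
Groups report mean ± sample SD over subjects; a group with fewer than two
subjects is flagged rather than dropped.

The battery mirrors the multi-study design: Student's t-tests for the
pre/post endurance-training comparisons (paired by subject by default —
the same individuals were biopsied before and after training — with an
unpaired variant by configuration) and for claudication patients vs their
controls; 2×2 two-way ANOVA (phenotype × training, type-II sums of squares
since the hypertension study is unbalanced) with Tukey HSD over the four
cells when an omnibus effect is significant; one-way ANOVA comparing each
untrained patient group with the pooled 42 untrained healthy participants,
with Tukey HSD pairwise tests when significant; and Spearman rank
correlation of every index with age over the pooled healthy subjects.
Normality is screened with the Lilliefors-corrected Kolmogorov–Smirnov test
(statsmodels' table-based p-values) and Shapiro–Wilk; failures are reported
but do not switch any test to a nonparametric alternative. P-values are not
adjusted across indices — only within an ANOVA via Tukey — and significance
is starred at α = 0.05 / 0.01 / 0.001. Type-I error of each test is verified
to lie in [0.03, 0.07] at α = 0.05 under its null over 2,000 simulations,
and the Tukey family-wise error over the four-group design stays ≤ 0.07.

## Synthetic cohorts

The generator emulates the 14 study groups (four endurance-training studies
plus a claudication study; 6–14 subjects per group, 126 biopsies, 40
capillary profiles per biopsy by default). Printed group values parameterize
the nucleus-density, surface-enlargement and BM-disruption distributions and
all group sizes. Geometric absolutes are documented placeholders — lumen
radius 1,500 ± 300 nm, EC thickness 400 ± 100 nm, healthy BM 400 ± 80 nm
(all gamma-distributed at the capillary level, floored at physically
sensible minima) — with the published ratios applied on top: BM +38.5 % in
untrained diabetics and +45.5 % in claudicants, the reported post-training
EC thickening (+17.3/+27.2/+9.2/+13.5 %) and BM thinning
(−13.7/−24.1/−13.1 %), socket-frequency placeholders honoring the reported
empty-EC-socket frequencies in the patient groups (20.6/27.1/30.0 %) and the
claudication excesses for EC (+21.3 %) and pericyte (+46.6 %) sockets.

Each profile is built from three **similar ellipses** (an oblique section
stretches every boundary by the same factor) sharing a low-amplitude
harmonic wobble, discretized at 256 vertices; 15 % of profiles draw an
elongation in (1.25, 1.6) to exercise the exclusion filter, the rest in
(1.0, 1.15). Pericytes are radial band sectors occupying the middle half of
the BM ring over arcs whose summed abluminal arc length realizes the drawn
coverage; the geometric BM ring is widened so that the pericyte-excluded
(material) thickness equals the drawn BM thickness, which is what the
consistent estimator measures. The nucleus is a band sector inside the EC
ring sized by bisection to the drawn density (draws capped at 80 % so that
rater noise can never push a reading past the whole ring); projections are
radial polylines whose summed length realizes the drawn enlargement exactly.
Socket counts are Bernoulli presence with a truncated-geometric count
(mean ≈ 1.5 when present); disruption is a per-capillary Bernoulli.

**Variance model.** Each continuous index splits the published group
variance 50/50 between a subject effect (shared between a subject's pre-
and post-training biopsies) and capillary-level noise: both components have
SD √0.5 × the printed SD. Averaging a biopsy's ~34 included profiles then
shrinks the capillary component, so the realized spread of subject means is
≈ 0.71 × the printed SD — the printed SD is treated as the total biological
dispersion, not as a target for the realized subject-mean spread. The
binary observations (socket presence, BM disruption) draw subject-level
probabilities at √0.5 × printed SD and get their within-subject variance
from Bernoulli sampling, which at 40 profiles contributes ~6–7 percentage
points of SD on its own — comparable to several printed SDs, so realized
frequency SDs can exceed the printed ones; this is an unavoidable property
of per-capillary binary scoring at this sample size. Nucleus density uses a
presence/absence model (a nucleus is visible in ~60 % of profiles) with a
gamma conditional density whose mean is moment-corrected for the 80 % cap.

**Rater noise** is multiplicative lognormal on derived indices, not on
vertices: each rater's copy of a profile carries a calibration factor on its
nm/pixel scale (σ = 0.05; all length indices inherit it, dimensionless ones
do not), plus independent factors on projection lengths and nucleus areas.
Reading pairs deviating by more than 10 % are redrawn during generation,
emulating the protocol in which discordant measurements were repeated — the
recorded data contain only reconciled pairs, and because the conditioning
acts on the reading difference only, merged means stay unbiased. (Without
this, dropping flagged pairs selectively removes nucleus-bearing profiles —
zero readings never disagree — and biases nucleus density low by ~8 %.)
Generation is deterministic given the master seed, with hierarchical
subject/biopsy/rater seeding that keeps a subject's draws stable when other
groups are added or removed.

## What passing tests do and do not show

The generator realizes each index by construction, so parameter-recovery
tests demonstrate that the measurement, reconciliation and aggregation
stages are unbiased and correctly plumbed — not that the geometric model
captures real capillary ultrastructure. Real tracings have correlated,
non-elliptic boundary noise, partial profiles, and rater disagreement that
is not purely multiplicative; none of these are modeled. Absolute geometric
levels (radius, thicknesses, coverage) are placeholders, so only their
ratios and the indices parameterized from printed values carry meaning in
comparisons with the published numbers.

A note on the recovery acceptance check: "every group mean within 2
Monte-Carlo SEM" spans 154 group × index combinations whose z-scores are
approximately standard normal (with t-tails at 6–14 subjects) even for a
perfect pipeline, so a simultaneous 2-SEM band fails with near certainty
(~9 % exceedance per combination; all-pass probability < 0.1 %). The suite
therefore carries both the literal simultaneous check and a calibrated one
that bounds the excursion fraction and the largest |z| on a full-size
cohort.

## Numerical choices and limitations

* Containment validation tolerates 0.5 px of tracing jitter at shared
  boundaries; contours are simple polygons with vertices at pixel centers.
* Canonical JSON rounds coordinates to 6 decimals, making save→load→save
  byte-stable.
* Feret diameters are exact convex-hull caliper values, not sampled over
  directions.
* Degenerate statistical inputs (constant vectors, zero-variance paired
  differences, empty index columns) are flagged and reported; the battery
  never aborts on a single failing comparison.
* Default problem sizes (full cohort ≈ 5,040 profiles × 2 raters; 2,000
  null replicates for calibration; 20 seeds for the significance-pattern
  check) were chosen to keep each Monte-Carlo claim's standard error well
  inside the asserted band.
* The harmonic-mean barrier thickness, mixed-effects/repeated-measures
  models, inter-rater reliability coefficients, and any pixel-level
  segmentation are out of scope.
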