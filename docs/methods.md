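# Methods

This note records the models, conventions and numerical choices behind
`petln`, and what the synthetic cohort can and cannot show.

## Data model

The unit of analysis is a histologically confirmed thoracic lymph node
(Mountain–Dresler stations 2, 4, 5, 6, 7, 10, 11, 12), carrying SUVmax,
SUVmean and SUVpeak plus a binary histology label. Each node belongs to a
patient with four reference uptakes measured once per scan: primary tumor,
liver (5 cm VOI), brainstem (2 cm VOI), and contralateral healthy lung
(5 cm VOI), all as SUVmax. Patient covariates encode the acquisition
protocol's inclusion windows (fasting glucose ≤ 8.3 mmol/L, uptake time
45–70 min, injected activity 226–245 MBq) and are validated on
construction. Nodes are treated as independent observations — cross tables
and ROC analysis are node-level, with no within-patient clustering
adjustment, matching how such cohorts are conventionally reported.

## SUV quantification

Volumes are 3-D grids with anisotropic spacing (default 1.5 × 1.5 × 5.0 mm,
a clinical whole-body PET reconstruction grid). Physical coordinates put
the origin at the center of voxel (0,0,0); axes (x,y,z) follow array axes
(0,1,2). NIfTI affines vary between tools, so this convention is fixed and
documented rather than inferred.

- **SUV scaling**: SUV = C·w/(A·2^(−t/T½)) with C the concentration
  (kBq/mL), w body weight (g), A injected activity (kBq), t minutes from
  injection to scan and T½ = 109.77 min for F-18 (configurable for other
  tracers); tissue density is taken as 1 g/mL.
- **VOI membership** is center-in-sphere with no partial-volume weighting:
  simple, unambiguous, and directly checkable against an exhaustive
  per-voxel oracle.
- **SUVpeak** is the EANM-style convention: the highest mean over a 1.0 mL
  sphere (diameter ≈ 12.407 mm) centered on any voxel center inside the
  VOI. The averaging sphere may extend beyond the VOI and is clipped only
  at the volume boundary. Consequently SUVpeak is bounded by the
  volume-wide maximum, not by the VOI's own SUVmax: for a VOI smaller than
  the averaging sphere sitting next to a hot region, SUVpeak can exceed the
  VOI's SUVmax. When the VOI encloses the averaged voxels (the clinical
  situation: the VOI covers the lesion), SUVmean ≤ SUVpeak ≤ SUVmax holds.

## Features and scores

The four ratio features divide the node SUVmax by the patient's reference
SUVmax values. All score conditions and classification rules use inclusive
≥. The quantified visual score evaluates, in order: node ≤ liver → 1;
liver < node ≤ primary → 2; node > primary → 3. In the degenerate case
primary < liver the rules are still applied in that order, so a node with
primary < node ≤ liver scores 1 (first match wins); the configuration is
logged since the ordering assumption fails there. The multifactorial score
counts the five threshold conditions; thresholds are data, not constants —
they default to the published values but can be re-derived on any cohort
with the ROC cut-off machinery, mirroring the original two-stage
construction (derive cut-offs, then freeze them as score conditions).

## ROC analysis

Positivity is value ≥ threshold throughout. The empirical ROC has one
operating point per distinct observed value plus the degenerate
(sens 0, spec 1) endpoint; the trapezoidal area equals the rank-sum
concordance with ties counted ½ (asserted against an O(n²) oracle). The
95% CI uses DeLong's placement-based variance by default; Hanley–McNeil is
available because legacy clinical software commonly reports it; the method
used is recorded in the report. The optimal cut-off minimizes
d = √((1−Se)² + (1−Sp)²) over finite thresholds, ties broken by higher
specificity then lower threshold (the published analysis is silent on
ties). Percentages are reported ×100, rounded half-up to two decimals as
clinical tables print them; raw fractions are retained, and tests compare
the unrounded values. A metric with an empty denominator is explicitly
`None`, never 0. Two-group class comparisons use the two-sided Mann–Whitney
U (asymptotic, tie-corrected): the reference summaries are
medians-with-ranges, so a rank test is the natural match; two identical
groups give p = 1.0.

## Synthetic cohort generator

The generator emulates the statistical structure of the clinical cohort:

- **Per-class feature distributions** are truncated log-normals. For a
  target median m and range (lo, hi): location = log m; scale maps the
  central 99.5% of the parent onto log(lo, hi) (σ = (log hi − log lo)/2z,
  z ≈ 2.807); truncation to (lo, hi) by rejection. Log-normals fit
  positive, right-skewed uptake data summarized as medians with ranges.
  Defaults are the published benign/malignant summaries (e.g. SUVmax
  medians 3.45 vs 11.00).
- **Prevalence and clustering.** 28.7% of nodes are malignant. Malignant
  nodes cluster in node-positive (N+) patients: a stratified count
  round(n·0.287/0.75) of patients is N+, and each N+ node is malignant with
  probability 0.75 (N0 patients are all benign). Clustering is how nodal
  metastases occur; the stratified patient count keeps the realized
  prevalence within a fraction of a point at cohort scale, where
  patient-level Bernoulli draws would let it wander.
- **Reference consistency.** Ratios are recomputed downstream as node
  SUVmax / patient reference, so references cannot be drawn independently
  of the ratio targets. Each organ's reference median is derived as
  (class truncated SUVmax median)/(class ratio median), conditioned on the
  patient's N-status, with log-normal patient noise (σ = 0.18). Malignant
  ratio medians are then exact by construction. Benign nodes inside N+
  patients see N+-calibrated references; a single minimax log-shrinkage on
  those nodes' SUVmax centers the resulting bias band, leaving per-class
  median biases of ≲3% (noise at ~1,200 nodes is of the same order). Node
  SUVmax draws are rejection-sampled until all four implied ratios lie
  inside the class ratio ranges, so generated values respect the published
  ranges.
- **Nodes per patient**: 1–6 with probabilities (.19, .27, .26, .14, .09,
  .05) — median 3, mean ≈ 2.8, matching 101 nodes from 37 patients.
- **Derived SUV statistics** are fixture conventions, not clinically
  calibrated: SUVmean = SUVmax·U(0.55, 0.85), SUVpeak = SUVmax·U(0.80,
  0.98), enforcing the partial-volume ordering. Short-axis sizes are
  log-normal (medians 10/15 mm benign/malignant) giving a cohort mean near
  13.7 mm.
- **Determinism**: one `numpy` generator seeded from the spec drives every
  draw in fixed order; identical spec + seed reproduces cohorts, CSVs and
  reports bit-identically.

### What the synthetic cohort does not show

Class-conditional feature draws are independent across nodes given the
patient's references; real within-patient correlation of uptake, real joint
dependence between SUVmax and each ratio, station-specific malignancy
rates, scanner noise and reconstruction effects are not modelled. End-to-end
AUCs on generated cohorts land around 0.94–0.98 — inside the plausible
(0.80, 0.99) band but above the clinical 0.86–0.94, because independent
draws understate the hard overlapping cases that real cohorts contain.
Passing calibration tests therefore shows the pipeline's arithmetic and
calibration are right, not that clinical performance would reach these
numbers.

## Problem sizes and tolerances

Oracle-equivalence tests run 100 random cohorts of up to 60 nodes (AUC vs
pairwise concordance at 1e−12; cut-off vs exhaustive search) and 50 random
phantoms of ~9×9×5 voxels against exhaustive-loop references. Calibration
checks use 425 patients (~1,200 nodes): per-class medians within ±10% of
targets, malignant fraction within ±3 points, AUCs in (0.80, 0.99). The
distribution-level Monte-Carlo check uses 50,000 draws (±2% on the median).

## Known limitations

- The published table contains two arithmetic misprints (SUVmax sensitivity
  89.67 vs 26/29 = 89.66; lung-ratio accuracy 81.89 vs 82/101 = 81.19);
  `reproduce_tables` reports the recomputed values and flags both.
- The liver/brainstem/lung reference convention follows the SUVmax-based
  definition used in the source tables; some institutions use liver SUVmean,
  which would shift the liver-ratio cut-off.
- DeLong CIs are Wald-type and clipped to [0, 1]; near-degenerate AUCs
  (perfect separation) collapse the CI to a point.
- Re-derived cut-offs on small cohorts are highly variable; the two cut-off
  modes exist precisely to keep that distinction visible.
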