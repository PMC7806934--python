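# Methods

This note documents the models and procedures implemented in
`lymphoscreen`, the parameter defaults and why they were chosen, the
numerical decisions, and what the synthetic data can and cannot show.

## The screening pipeline

A screened blood sample is a well of fixed white blood cells stained in
three fluorescence channels: nuclear (blue), pan-leukocyte (red) and
marker (green, anti-STAU2). Twelve fields per well are imaged at 20×. The
pipeline reduces each well to two statistics — average marker intensity
and percentage of marker-positive cells — and evaluates cut-offs on those
two axes over a cancer/normal cohort.

### Blob detection and measurement (`quantify`)

Each channel is binarized at `detection_threshold` (default 140 grey
values, the lower bound of the capture intensity range; the original
acquisition software's threshold is not published). 8-connected components
are measured with scikit-image region properties:

- **perimeter** — the Crofton-corrected boundary estimate
  (`perimeter_crofton`, 4 directions) scaled by `um_per_px`. For rasterized
  disks of radius ≥ 5 px this estimator stays within ±10% of the true
  circumference 2πr, which the test suite asserts directly.
- **mean grey value** — mean pixel intensity inside the component.

A blob is *captured* when perimeter ∈ [25, 200] µm and mean grey ∈
[140, 300]; a green blob makes its cell *positive* when perimeter ∈
[25, 150] µm and mean grey ∈ [150, 280]. All bounds are inclusive: the
source ranges are written without open/closed notation, and inclusive
bounds make boundary behaviour deterministic. The capture and positivity
intensity scales are treated as the same grey-value axis.

### Colocalization

A cell is a red (leukocyte) blob; its marker status comes from a green
blob "in the same position". Positionality is a centroid-distance rule:
green blobs are assigned greedily — globally closest remaining
(green, red) pair first — to unassigned red blobs within
`coloc_max_centroid_dist_um` (default 5 µm, about half a lymphocyte
diameter; the original tolerance is unpublished). Ties break by (y, x)
order, making the matching deterministic. Unmatched green blobs are
discarded with a logged count.

### Per-sample statistics

`pct_positive = 100 · n_positive / n_cells` over the pooled cells of a
well's fields (order- and duplication-invariant by construction).

`avg_intensity` has two modes because the protocol's literal wording —
"intensity of positive cells divided by the intensity of positive and
negative cells" — is a dimensionless ratio ≤ 1 when negative cells carry
no green signal, while the published cohort values (e.g. 110.50) are on
the grey-value scale:

- `mean_of_positives` (default) — arithmetic mean of green mean-grey over
  positive cells; scale-compatible with the published summaries.
- `ratio_as_stated` — the literal ratio, preserved for fidelity.

Zero cells (or zero positives in the default mode) flags the statistic
undefined rather than raising, so empty wells survive batch processing.

Between-batch ("interassay") adjustment is multiplicative: each batch's
intensities are scaled by reference-control ÷ batch-control, anchoring the
shared positive-control well. The original adjustment method is not
specified beyond the use of cocultured-PBMC positive samples; a
multiplicative anchor is the simplest rule that equalizes the control
across batches without recentring the negatives.

### Cohort evaluation (`cohort`)

Group comparisons use the independent-samples t-test, Welch by default
(the source names only "independent sample t-tests"; Welch is the safer
default under unequal variances, and the pooled-variance form is an
option). ROC curves use the rule score ≥ threshold ⇒ positive, one point
per distinct score, AUC by trapezoid — equal to case–control concordance
probability with ties counted half, which the tests verify by brute force.

The two-axis quadrant rule calls a sample positive when intensity ≥ x OR
pct ≥ y (inclusive on the positive side; the source shows only quadrant
shading). With y = +∞ it degenerates to the single-axis intensity rule
and reproduces the corresponding ROC point exactly.

Published operating points are reconstructed into 2×2 tables via
`confusion_from_rates` with round-half-up — the published counts appear
only in a figure, so reconstruction from printed rates and group sizes
(358 cancer / 363 normal) is the canonical path. Derived metrics:
sensitivity, specificity, PPV, NPV, accuracy, odds ratio with Woolf
95% CI, chi-squared p-value without continuity correction (the original
analysis tool is named but not the exact test variant). A
Haldane–Anscombe +0.5 on all cells handles zero cells, flagged in the
output.

### Risk assessment (`risk`)

Posterior disease probability by Bayes' theorem, computed in odds space
(pre-test odds × likelihood ratio) for stability at screening prevalences
of order 10⁻³–10⁻⁴. The probability-form and odds-form agree to machine
precision (property-tested). At the published operating point
(sens 82.96%, spec 83.47%) and prevalence 1/220 the posterior is 2.240%;
the originally reported 2.25% reflects rounding of intermediate inputs,
and both printed-rate and exact-count inputs are accepted.

### Expression intersection (`intersect`)

Marker discovery asks whether genes called up-regulated in one
case-control study are also up-regulated in another (or fall in a fixed
candidate list, e.g. genes containing a LINE-1 element). Per gene: an
equal-variance two-sample t-test (the classic microarray convention of
the published intersection tool; Welch optional), direction by sign of
the mean difference when p < α, α = 0.05 per gene with no
multiple-testing correction (configurable) — matching the conventions of
the original tool as implied by its reported gene counts. The 2×2
co-occurrence table over the shared gene universe is tested by
chi-squared when all expected cells are ≥ 5, otherwise Fisher's exact
test; odds ratios use Haldane +0.5 on zero cells. Genes absent from one
study are dropped, not imputed. A margin entirely of zeros (e.g. a list
covering the whole universe) is flagged degenerate with p = 1.

## Synthetic data: what it emulates and what it does not

### Field images

Cells are filled disks with uniform interior intensity, so the true
perimeter (2πr) and true mean grey value are analytically known — this is
what makes exact ground-truth oracle tests possible. Placement rejects
disks whose centre distance is below the sum of radii plus a 2 px guard
(at exactly the sum, rasterized disks can touch and merge into one
component, breaking the one-blob-one-cell correspondence). Defaults:
512×512 px fields at 0.65 µm/px (a typical 20× widefield scale; the
original pixel calibration is unpublished, so it is configurable
everywhere), radii 5–12 µm (circumference 31–75 µm, inside both perimeter
ranges), per-cell intensities uniform on [170, 250] grey values (inside
both intensity ranges; no per-cell intensity distributions are published,
so this is a design choice, not a source fact), Gaussian background noise
(SD 2 grey values by default), 8-bit depth. Exactly
`round(positive_fraction · n_cells)` cells receive a green disk.

Not simulated: optics (PSF, chromatic shift), staining chemistry,
illumination fields, touching-cell clumps, plate spatial effects.
Consequently, passing the image-pipeline tests shows the measurement
chain is correct on well-separated, uniform cells — not that detection is
robust to the segmentation pathologies of real micrographs.

### Cohorts

Per sample, (avg_intensity, pct_positive) is drawn from a correlated
bivariate normal truncated to intensity ≥ 0 and pct ∈ [0, 100],
truncation by resampling (clipping would pile mass on the boundaries and
bias the means). The published group moments — cancer 110.50 ± 23.38 and
61.87 ± 12.44, normal 56.47 ± 32.03 and 33.02 ± 18.10 — are taken as the
moments of the *truncated* law: the underlying normal parameters are
solved by moment matching (2-D Gauss–Legendre quadrature of the truncated
moments inside a root finder). This matters: for the normal group about
4% of an untruncated N(56.47, 32.03²) lies below zero, and resampling
without calibration would inflate that group's mean by ≈ 2.8 grey values.
With calibration, 10,000-sample groups reproduce the configured means
within 3 standard errors, which the acceptance tests assert.

The default correlation between the two statistics is ρ = 0.95, chosen to
satisfy the published R² > 0.9 bound with margin (only the bound is
published). Replicate-set labels (the original cohort was measured in 10
double-blinded sets) are optional strata with no further modelling.

The cohort generator draws the two statistics directly; it does not
simulate the per-cell measurement generating them, so cohort-level tests
validate the classification and metric arithmetic, not the image chain.
Both single-axis behaviour (sensitivity ≈ 80.6% at intensity 90.28, the
Gaussian tail of the cancer law, vs 81.28% published) and the quadrant
rule's operating point (≈ 82% / 82% vs 82.96% / 83.47% published) emerge
from this bivariate model rather than being targeted.

### Expression pairs

Genes × samples matrices of i.i.d. Gaussians, with planted shared-up
genes shifted by `effect_size · noise_sd` in the cases of both studies
and study-specific genes in one. Defaults: 1,000 genes, 20 samples per
group, 50 shared + 50 per-study planted genes, effect size 2 (recovery of
≥ 80% of the planted shared set at these settings was verified by
simulation). The companion gene list draws `list_enrichment` (default
0.8) of its entries from the planted shared genes. No probe-level
structure, batch effects or inter-gene correlation are simulated, so the
null-calibration results speak to the 2×2 machinery, not to microarray
normalization. The original studies' gene counts (709, 262, the 14-gene
final list) depend on external repository data and are format references
only.

## Problem sizes and determinism

Every generator and analysis is deterministic given its seed. The test
suite and the acceptance script use sizes chosen to make the statistical
assertions sharp while staying lightweight: 10,000 samples per cohort
group (standard errors ≈ 0.2–0.3 grey values on the means), 12 fields ×
40 cells for the image pipeline, 1,000 replicates at 2,000 genes for
intersection null calibration (the scale at which the chi-squared path is
exercised; at Fisher-exact scales the p-value is discrete and
conservative, and a uniformity bound is not the appropriate check).

## Known limitations

- The perimeter estimator's small-radius bias (< 5 px) is outside the
  asserted envelope; at 0.65 µm/px the 25 µm capture floor corresponds to
  ≈ 6 px radius, just above it.
- Greedy colocalization is not globally optimal for dense fields; with
  the non-overlap constraint of the simulator it coincides with optimal
  matching, and the tests verify this on small instances only.
- The two intensity-statistic modes cannot be reconciled without knowing
  how the original software scaled its ratio; both are provided and the
  mode is recorded in every output.
- Truncated-moment calibration assumes the bivariate-normal shape; real
  cohort distributions (e.g. the bimodality visible in published scatter
  plots) are not modelled beyond the two group laws.
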