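# Methods

## Imaging model

A brightfield H-DAB slide is modeled as two absorbing chromogens over a
white background. Per channel, optical density is OD = −log₁₀(max(I, 1)/255)
— the 1-intensity-unit guard keeps OD finite at I = 0 (cap ≈ 2.407). Stains
mix additively in OD space, so per-pixel concentrations follow from solving
the 3×3 system od = c·M, where M stacks unit stain vectors. The default M
uses the published Ruifrok–Johnston H-DAB directions, normalized, with the
unit cross product as residual channel; any unit, invertible basis can be
supplied. Negative concentrations (noise pushing a pixel outside the stain
cone) are clamped to zero after solving; the pre-clamp solution is exact and
is what round-trip tests check. `deconvolve_stains` preserves float32 input
(cheap on large images) and promotes everything else to float64.

Nucleus detection operates on the combined nuclear map (hematoxylin + DAB
concentration): Gaussian smoothing at σ = 1 px, fixed threshold 0.15,
connected components, and an optional distance-transform watershed split
seeded at local maxima ≥ 4 px apart. Components under 10 µm² (converted to
px² via mpp) are dropped. Per-component stain means are taken over the
*unsmoothed* concentration maps; because the smoothed mask carries a thin
zero-concentration rim, absolute means are slightly diluted while stain
ratios are preserved — the positivity decision is therefore a threshold on
mean DAB concentration (default 0.3, strict inequality, ties negative) that
sits between the two class levels rather than at their nominal values.
Raising the threshold can only reduce the positive count. None of these
segmentation defaults comes from a published protocol; they are this
package's declared operating point, chosen so that the generator's
well-separated nuclei are recovered exactly.

Isotropic microns-per-pixel is assumed; anisotropic TIFF resolution tags are
rejected with an explicit error. An mpp passed explicitly always overrides
file tags.

## Tiling and indices

The tile grid is anchored at the top-left corner of the annotation's
bounding box (the anchoring is arbitrary but fixed, so results are
reproducible); tile side = round(500 µm / mpp) px; a tile is kept iff its
box intersects the region polygon, so partial edge tiles are included —
they contain tumor, and they rarely reach the 500-cell hot-spot criterion
anyway. Boxes are half-open; a centroid sitting exactly on the grid's far
edge is clamped into the last row/column so in-region detections are
partitioned exactly. Membership is decided by the centroid alone (polygon
boundary counts as inside), which prevents double counting across tile
borders.

Hot-spot index: qualifying tiles (≥ 500 cells) are ranked by
percent-positive descending, ties broken by larger cell count then (row,
col) order — deterministic, favoring better-sampled tiles. The index is the
unweighted mean of the top five; with 1–4 qualifying tiles the mean runs
over those (flagged as fallback), with none it is undefined rather than
zero. Whole-slide index: unweighted mean of per-tile percentages over tiles
with ≥ 1 cell. Zero-cell tiles are excluded (0/0 is undefined; treating
them as 0% would deflate sparsely annotated regions). This is deliberately
a macro mean of tile ratios, not the pooled cell-level ratio. Outputs round
to 2 decimals; internal precision is full.

## Agreement statistics and risk groups

Lin's CCC is computed with population (1/n) moments; the sample (1/(n−1))
convention changes nothing at the level of the identities tested
(|CCC| ≤ |r|, equality iff means and variances match). Pearson's r and its
two-tailed p (t transform, n−2 df) come from scipy. Zero-variance series
raise an explicit undefined-statistic error.

Risk groups partition [0, 100]: low < 18, high ≥ 31, everything else —
including non-integer scores in (30, 31), a gap the integer-valued cut-point
convention leaves open — is intermediate. The confusion matrix follows the
asymmetric convention in which low-risk is the "positive" test outcome:
TP = correct low, TN = correct high, FP = high called low, FN = low called
high; pairs with an intermediate label on *either* side are excluded and
counted. Metrics with a zero denominator are reported as missing with a
flag, never as 0 or 100. Cohort-table percentages round half away from zero
at one decimal.

## Forest harness

The regression forest uses scikit-learn's RandomForestRegressor with the
published harness settings: 1000 trees, per-tree bootstrap draws of 40
records (with replacement), m_try feature candidates per split (12 for the
13-variable chart set, 15 when the three RT-PCR expression scores are
added), minimum node size 5, no depth cap. Ordinal variables (grades,
Allred, intensity) are encoded as integers. Missing values raise
immediately; callers drop incomplete records first (the CLI does this and
logs the count).

%IncMSE for predictor v is 100·(MSE_perm(v) − MSE_base)/MSE_base on
*held-out* records with a seeded permutation of column v — the relative
form matches the statistic's name and preserves ranking semantics; the
classic tree-level OOB averaging is a known alternative that differs only
in bookkeeping. A zero baseline MSE (perfect fit) switches the report to
absolute MSE increases with a flag. Noise predictors score near zero and
may go negative.

Cross-validation: per round, a seeded 50/50 split without replacement
(train receives the ceiling half of an odd cohort), fit, predict the test
half, clip predictions to [0, 100], map both predicted and actual scores to
risk groups, and tally the confusion matrix above. Rounds with no low/high
pairs contribute NaN and are excluded from that metric's mean ± sd, with
the count reported — small high-risk groups make per-round specificity
noisy, which is visible in its large standard deviation. Round seeds derive
from a single master SeedSequence, so an identical master seed reproduces
the full report byte for byte.

## Synthetic data

Slides: nucleus centers are a Poisson draw (base density, plus surplus
density inside each hot-spot disk) thinned to a hard core of 3× the maximum
nucleus radius — 1.5× the maximum diameter — so rendered nuclei can never
touch and the detection-count oracle is exact. Requests whose nominal
density exceeds the random-sequential-adsorption jamming estimate
(≈ 0.547/d²) raise a generation error. Each nucleus is Bernoulli-labeled
(p_hot inside a disk, p₀ outside) and rendered as a jittered ellipse with
class-specific hematoxylin/DAB concentrations, forward-synthesized through
the same default stain basis the analyzer inverts — a deliberate closed
loop; passing a perturbed basis to either side tests robustness separately.
Gaussian intensity noise (sd 2.5 of 255) is added before quantization.

Default slide: 3 × 3 mm at 1 µm/px, base density 550 nuclei/mm², two
hot-spot disks of radius 400 µm and density ×6 centered on tile centers
(positivity 0.85 and 0.55 vs. 0.12 background), nucleus radii 2.4–3.2 px.
Hard-core thinning leaves roughly 60% of the nominal hot-spot density, so
hot tiles hold ≈ 550–600 cells and qualify while background tiles (≈ 140
cells) do not — matching the regime where hot spots are rare, qualifying
tiles are a minority, and the hot-spot index sits well above the
whole-slide index. What the generator does *not* emulate: staining
gradients, tissue folds, scanner variation, overlapping or out-of-focus
nuclei, stromal/immune cell populations. Passing recovery tests therefore
demonstrates correctness of the scoring logic, not segmentation robustness
on real tissue.

Cohorts: grade, nuclear grade, differentiation and receptor scores are
drawn from frequencies typical of an HR+/HER2− early-stage cohort; mitotic
score tracks grade. Ki67 is lognormal with location rising in grade
(+0.40/level) and mitotic score (+0.50/level) and falling in ER (−0.12 per
Allred point) and PgR (−0.06) — reproducing the qualitative interaction
structure of such cohorts, with no claim of distributional fidelity. The
Recurrence Score is a linear combination dominated by Ki67 (default
rs = 6 + 0.9·ki67 + 1.2·(grade−2) + 1.5·(mitotic−2) − 0.8·(er_allred−7)
− 0.5·(pgr_allred−6) + N(0, 5), truncated to [0, 100]), calibrated once so
the risk-group split lands near 62/28/10 low/intermediate/high. The
`single_signal` variant (rs = 5 + 0.8·ki67 + N(0, 1.5)) is the known-answer
benchmark for the harness: any correct implementation must recover near-
perfect low/high classification and rank Ki67 first in importance. The two
extra chart variables completing the 13-predictor set (lymphovascular
invasion, positive node count) are generated as uninformative noise; the
predictor list is configuration, not code.

## Problem sizes and numerical choices

The validation suite runs five default slides (≈ 6000–7000 nuclei each) for
oracle-recovery checks and 100 cross-validation rounds at the full
1000-tree setting (the per-round importance-ranking frequency uses a
200-tree forest, which leaves the ranking unchanged) — sizes chosen so the
whole suite completes in minutes on a single core while keeping every
statistic comfortably inside its sampling tolerance. Stain round-trips are
checked to 1e-6 (float64 achieves ~1e-15); agreement statistics against
brute-force summation to 1e-12; index-recovery to 2 percentage points,
which absorbs residual segmentation/label noise at the default class
separation.

## Known limitations

No pyramidal WSI containers (SVS/NDPI) or lazy tiling: images must fit in
memory. No stain normalization across scanners, no learned segmentation —
heavily overlapping nuclei on real tissue will under-count. H&E↔IHC
registration is out of scope; annotations are assumed already transferred
to the Ki67 image. Confidence intervals for CCC and the nonparametric
group-comparison tests are not implemented.
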