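# Methods

## Synthetic spot data

The generator emulates the statistical structure of a tumor section on a
Visium-like array. Spots sit on a hex lattice (rows offset by
`spacing/2`, row pitch `spacing·√3/2`, so interior spots have six
equidistant neighbors — the geometry behind the default k = 6 graph); a
square grid is available for geometric oracles.

**Cell-type fractions.** The malignant fraction is a sigmoid of distance
`d` to the core center, `m_i = 0.95 · logistic((R − d_i)/s)` with core
radius `R` and sharpness `s` (defaults R = 6 spacings on a 20×20 lattice,
s = 1): ≈0.95 deep in the core, ≈0 at the margin, monotone in `d`. The
non-malignant remainder `1 − m_i` is divided among endothelial, T-cell and
"other" components proportionally to independent Gaussian-kernel-smoothed
white-noise fields (bandwidth 2·spacing, matching the neighborhood scale
of the k = 6 graph), so every row lies exactly on the simplex and the
malignant fraction itself is untouched by the allocation. This mimics the
output of a deconvolution method such as SpaCET without running one.

**Ground-truth exhaustion field.** A convex mixture
`e = γ·smooth(m) + (1−γ)·u` of the smoothed malignant field and an
independent smooth field `u`. The single knob γ ∈ [0, 1] sets the
cross-spot coupling between exhaustion and malignancy: γ = 0 decouples
the fields, γ = 0.9 is the "strong co-aggregation" study condition.

**Counts.** Negative-binomial with dispersion r = 2 (var = μ + μ²/r) and
lognormal per-spot library factors (σ = 0.3, mean total ≈ 5,000 counts).
Per-gene relative rates are `base + β·field`: SLC1A3 follows the
malignant field (β_mal = 5), CD8A and a configurable exhaustion panel
(default PDCD1, HAVCR2, LAG3, CTLA4, TIGIT, TOX — a stand-in; no
canonical panel is fixed here) follow the exhaustion field (β_ex = 5),
and CD274/TGFB1/IL10/IDO1 follow `endothelial·malignant` (β_is = 5),
which is exactly the TEC phenotype. Fifty unstructured noise genes with
lognormal base rates complete the panel. Effect sizes of 5 relative to a
base rate of 0.5 make the structured genes clearly, but not
deterministically, field-driven at r = 2 — "strong effects" at realistic
count noise.

**Survival fixture.** Exponential event times with
`log-hazard = α + effect · 1[expression > median]` averaged over the
planted adverse genes, independent exponential censoring (≈20–30%
censored at the defaults), lognormal expression. `effect = +1.5`
corresponds to a strong adverse marker; `effect = 0` gives the null.

What the generator does **not** emulate: H&E imagery, segmented
single cells, batch/section effects, zero-inflation beyond the NB, or
spatially varying capture efficiency. Passing tests therefore show the
statistics behave correctly under the assumed structure, not that the
biological claims hold in any clinical cohort.

## Normalization and scores

Counts are depth-normalized to 10,000 per spot and log1p-transformed
(`cp10k_log1p`) before scoring; `method="none"` passes raw counts
through, since analyses of this kind have used the raw scale for the
malignant weighting and the choice is left to the user. The pure
malignant score multiplies the (normalized) marker expression by the
malignant fraction; signature scores are per-spot means over the panel
genes present (absent genes are logged, duplicates dropped).
Stratifications are rank-based: median split (ties to "low", i.e. high
requires strictly exceeding the threshold) or top/bottom-q quantile split
with linear-interpolation quantiles; thresholds are recorded in the
label object for provenance.

TEC/NEC: vascular-enriched spots are the top 50% by endothelial fraction
(≥ the median, so a constant endothelial field marks every spot
vascular); within that subset, TEC = malignant fraction ≥ its 70th
percentile, NEC = ≤ its 30th percentile, computed within the subset.

The exhausted-T-cell niche used by the proximity test is the set of spots
with both the exhaustion score and CD8A above their medians.

## Spatial statistics

**Weights.** k-nearest-neighbor by Euclidean distance, binary then
row-standardized to 1/k; no self-neighbors; exact distance ties broken by
ascending spot index so degenerate lattices give deterministic graphs.
The graph is listwise (asymmetric); row standardization is a flag.

**Bivariate Moran's I.** Both variables are z-scored with the population
SD; `I = (1/n) z_xᵀ W z_y`. This normalization makes mean(local I) equal
the global I exactly and gives ±1 on the two-spot antithetic/aligned
pairs. Significance by Monte-Carlo permutation of y (x and W fixed),
`p = (1+b)/(n_perm+1)`; with the default 999 permutations the attainable
minimum is 0.001. The permutation direction (y, not x) matches the
question "does exhaustion co-locate with the malignant field"; the
default alternative is "greater" because the claim under test is positive
co-aggregation.

**LISA.** `I_i = z_x,i · lag(z_y)_i`, quadrant from the signs of
`(z_x,i, lag(z_y)_i)` with HH = both positive (the convention that makes
HH the "hi/hi domain"). Local p-values by conditional permutation: spot
i's own value is held while its k neighbor values are drawn from z_y
excluding spot i; a single permutation table is shared across spots and
shifted around each spot's own index. The one-sided local p is taken in
the direction of the observed deviation from the permutation mean and
flagged at α = 0.05 after Benjamini–Hochberg adjustment across spots.

**Rank tests.** Mann-Whitney U with midranks; exact p by
dynamic-programming enumeration of the full labeling distribution when
max(n₁,n₂) ≤ 10 and there are no ties, otherwise a normal approximation
with tie correction and 0.5 continuity correction. Wilcoxon signed-rank:
zeros dropped, exact enumeration of all 2^m sign patterns for m ≤ 12
(midranks handled by enumerating the realized rank vector), otherwise the
midrank-form normal approximation (mean Σr/2, variance Σr²/4). Two-sided
p-values double the smaller tail, capped at 1. The "paired Wilcoxon" used
for the TEC/NEC contrast is the signed-rank test over patient-level
paired differences of stratum means.

**Geometry.** Distance-to-core is the minimum Euclidean distance to the
core set (0 inside); annular zones are `floor(d / zone_width)` with
zone width defaulting to 2·lattice pitch; the core-to-margin trajectory
is a LOESS fit (tricube weights, local degree-1, no robustness
iterations, span 0.75 by default) of a score against distance, evaluated
on a regular grid. The malignant core itself is defined as spots with
malignant fraction ≥ 0.5 **and** pure malignant score ≥ its 70th
percentile; both thresholds are configurable and recorded.

## Survival and the funnel

Kaplan–Meier product-limit estimator with median = smallest time at which
Ŝ(t) ≤ 0.5 (NaN if unreached); with no censoring it reduces to
1 − ECDF. Two-group log-rank: pooled event times, hypergeometric variance
`d(n₁/n)(1−n₁/n)(n−d)/(n−1)` with the standard pooled tie handling,
χ²₁ p-value; the *direction* for the high group is the sign of O − E,
which stays well-defined when medians are unreached. The funnel applies
strict inequalities at the DEG boundaries (p < 0.05, |logFC| > 1.2 —
boundary rows are excluded), intersects DEG cohorts first and then the
splicing / pseudotime / surfaceome stages (order-independent), and
retains a candidate only if the log-rank p is < 0.05 with adverse
direction in every cohort supplied. The surfaceome reference is a
user-supplied gene list; no specific database is bundled.

## Numerical and design choices

- One integer seed drives simulation, permutation and LISA; identical
  config + seed reproduces byte-identical output files.
- Quantiles use numpy's linear interpolation; threshold ties go to the
  lower stratum throughout.
- `n_perm ≥ 19` is enforced (below that α = 0.05 is unattainable).
- kNN uses an exact dense all-pairs sort up to 2,048 spots and a KD-tree
  with deterministic tie resolution beyond.
- Degenerate inputs fail loudly: constant vectors cannot be z-scored or
  median-split, empty core/niche masks and all-zero paired differences
  are errors, malformed files raise format errors with file context.

## Calibration, power, and problem sizes

The test suite verifies, at sizes chosen to keep the default run fast:

- type-I error of the Monte-Carlo Moran test on 10×10 lattices over
  1,000 replicates under the generator's exchangeable null (γ = 0 and all
  effect sizes 0, so the exhaustion score is iid across spots), expected
  in [0.03, 0.07];
- log-rank type-I error at n = 100 over 500 replicates, same band;
- strict monotonicity of the mean estimated I over γ ∈ {0, 0.3, 0.6, 0.9}
  (12×12 lattices, 20 seeds per level);
- power: the γ = 0.9, 400-spot condition reaches I > 0 at the minimum
  attainable p, and the proximity test reaches p ≤ 10⁻³.

**Limitation — permutation inference with autocorrelated y.** The
Monte-Carlo test's null is exchangeability of y across spots. When y is
itself spatially autocorrelated but independent of x (γ = 0 with a
nonzero exhaustion effect), permutation destroys y's autocorrelation and
the test is anticonservative — measured rejection ≈ 0.10–0.17 at nominal
0.05 under raw-scale scoring on 10×10 lattices. Depth normalization adds
a second subtlety: a dominant structured gene (SLC1A3 in the core) shifts
the compositional share of all other genes, imprinting a *negative*
association between the malignant and exhaustion scores even when the
underlying fields are independent. Both effects are properties of the
statistic as used in the field (the same permutation scheme underlies
spdep's Monte-Carlo test), not of this implementation; interpret borderline
p-values accordingly, and prefer the γ-recovery / effect-size view when
comparing sections.
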