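# spotniche

Spatial co-aggregation statistics for tumor–endothelial–T cell niches in
spot-based spatial transcriptomics (10x Visium and similar arrays).

## The problem

In glioblastoma, malignant cells expressing the glutamate transporter
SLC1A3 appear to organize an immunosuppressive perivascular niche: tumor
cells educate nearby endothelium, which upregulates immunosuppressive
mediators (CD274, TGFB1, IL10, IDO1) and blunts T-cell activity, leaving a
spatial signature in which T-cell *exhaustion* co-aggregates with the
malignant compartment. Testing that signature on spot arrays is
complicated by the multi-cellular resolution of each spot: raw spot-level
expression mixes tumor, stromal and immune signal.

`spotniche` implements the statistical toolkit for this question:

- **Pure malignant score** — spot expression of a marker gene weighted by
  the deconvolved malignant cell fraction, `score_i = x_i(SLC1A3) · f_i(mal)`,
  stripping stromal signal from multi-cellular spots.
- **Bivariate Moran's I** — with z-scored variables and a row-standardized
  k-nearest-neighbor weight matrix `W` (k = 6 by default),

  `I = (1/n) Σ_i z_x,i Σ_j w_ij z_y,j`

  measures whether high malignant score at a spot co-occurs with high
  exhaustion in its neighborhood. Significance via Monte-Carlo permutation
  of `y` (999 permutations; `p = (1+b)/1000`).
- **Bivariate LISA** — per-spot decomposition `I_i = z_x,i · lag(z_y)_i`
  with HH/HL/LH/LL quadrant labels, conditional-permutation p-values and
  Benjamini–Hochberg adjustment, mapping the SLC1A3^hi/Exhaustion^hi domains.
- **Proximity and gradient analyses** — minimum Euclidean distance to the
  malignant core or to exhausted-T-cell niche spots, one-sided Wilcoxon
  rank-sum comparisons, concentric annular zones, LOESS core-to-margin
  trajectories.
- **TEC/NEC contrast** — vascular-enriched spots (top 50% endothelial
  fraction) stratified by co-existing malignant fraction (top vs bottom
  30%) into tumor-associated vs normal-like endothelial areas; paired
  intra-patient Wilcoxon signed-rank tests on the mediator panel.
- **Candidate prioritization funnel** — strict differential-expression
  thresholds (p < 0.05 and |logFC| > 1.2), set intersections with splicing /
  pseudotime / surfaceome lists, and survival-based filtering with a
  from-scratch Kaplan–Meier estimator and log-rank test (a candidate is
  kept only when high expression is significantly *adverse*).
- **Synthetic data generator** — Visium-like hex lattices with a sigmoid
  malignant core, smooth endothelial/T-cell fields, negative-binomial
  counts, and a single coupling knob γ ∈ [0, 1] that sets the ground-truth
  cross-correlation between the exhaustion field and the malignant field,
  so every statistic above is testable against known truth.

The rank-sum and signed-rank tests use exact enumeration for small
samples (full labeling / sign-pattern enumeration) and tie-corrected,
continuity-corrected normal approximations otherwise.

## Worked example

```python
import spotniche as sn

cfg = sn.SimulationConfig(n_rows=20, n_cols=20, coupling_gamma=0.9, seed=3)
lattice, fractions, truth, expr = sn.simulate_dataset(cfg)
bundle = sn.run_spatial(lattice, expr, fractions, sn.RunConfig(seed=3))
g = bundle["global"]
print(g["moran_I"], g["moran_p"], g["proximity_p"])
```

Running `python examples/coaggregation_analysis.py` prints:

```
spots: 400, malignant core: 118 spots
bivariate Moran's I = 0.551  (one-sided MC p = 0.001)
LISA: 83 significant spots, quadrants: {'LL': 43, 'HH': 40}
proximity test (high vs low malignant score): p = 1.15e-38; median distance to exhausted niche 1.00 vs 1.73
```

I = 0.551 at p = 0.001 (the attainable minimum with 999 permutations) is
strong positive spatial co-aggregation of the malignant SLC1A3 score and
the exhaustion signature; the LISA map localizes it to coherent
high/high (core) and low/low (margin) domains; the proximity test shows
SLC1A3-high spots sit closer to exhausted-T-cell niches (median lattice
distance 1.00 vs 1.73). The other scripts in `examples/` walk through the
annular-zone gradient, the TEC/NEC mediator contrast, and the
prioritization funnel.

A thin CLI wraps the same pipeline:
`spotniche simulate out/ --seed 3`, `spotniche spatial ...`,
`spotniche prioritize ...`, `spotniche report out/`.

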