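# Methods

This note documents the models and procedures implemented in `mimir`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Normalization

Counts are scaled per cell to a fixed total (default 15,000), incremented by
1 and log2-transformed. A zero count maps to exactly 0, and
`Σ (2^value − 1) = 15,000` per cell to numerical tolerance, which the test
suite asserts. All downstream stages consume this log2 scale; no further
pseudocount is added anywhere (log fold changes are differences of these
values).

## Trajectory enrichment

The pseudotime axis is cut into `n_segments` equal-width intervals (default
15). Segments with fewer than `min_cells` cells (default 60) are fused with
neighbours. "As even as possible" is made precise as a two-level objective:
among all contiguous fusion plans whose groups each reach `min_cells`, fuse
as little as possible (maximise segment count), then minimise the variance
of the final counts. A naive single-objective variance minimisation is
degenerate — one all-covering segment has variance zero — which is why the
lexicographic form is used. The search is exhaustive (2^(n−1) plans) for up
to 15 initial bins and falls back to greedy smallest-neighbour merging
beyond that; fewer than `min_cells` cells in total collapse to one segment.

Marker calling per window scores each gene as a classifier of group vs
background cells by the area under the precision–recall curve. The
"expected value from randomized data" dividing the AUCPR is taken as the
positive-class prevalence — the analytic expectation for an uninformative
ranking, deterministic and parameter-free; a permutation null is available
in the tests and agrees with prevalence to ±0.02 at n = 400. Ties contribute
as blocks (the average-precision-with-ties convention), so constant scores
yield exactly the prevalence. Detection means a nonzero normalized value
(raw count ≥ 1). Thresholds: detection fraction ≥ 0.1, AUCPR ratio ≥ 2
(trajectory mode) or 7.5 (stage mode), logFC > 0.3, all exposed as
parameters. Trajectory mode admits genes passing in the final segment or in
at least two segments; stage mode admits any-window passers; the per-cell-
type gene set is the union across datasets.

Term over-representation uses the one-sided exact hypergeometric tail
against a user-supplied background, with no multiple-testing correction
(callers who need one can correct the returned p-value column).

## Expression similarity

Profiles are per-segment means of log2 normalized expression over trajectory
cells, optionally dropping the earliest (pre-specification) segment. The
default distance is the Jensen–Shannon divergence itself (not its square
root), base-2 logs, on sum-normalized profiles, hence bounded by 1.
Distances are scaled by `d′ = 0.95·d/max(d)` and similarity is `1 − d′`.
This zero-preserving scaling (rather than min–max) keeps identical dynamics
at similarity exactly 1 whenever the minimum observed distance is positive;
a `minmax` variant is provided for comparison. The scaling makes S_exp
invariant to a global rescaling of distances and monotone decreasing in
distance.

## Functional similarity

Wang's semantic similarity is computed on the ontology DAG with relation
weights is_a = 0.8 and part_of = 0.6 (the measure's standard constants);
S-value propagation over multiple parents takes the maximum over paths.
Gene-level similarity is the best-match average of term similarities; a gene
unannotated in a database contributes a *missing* channel for its pairs, not
a zero. Channels are combined under the fixed prior p = 0.41 by the
complement-product formula; channels at or below the prior are clamped to
zero contribution, so any evidenced pair sits at or above p, a channel of 1
is absorbing, and all-prior channels leave the score at p. Pairs with no
channel from any source get S_fun = 0 rather than p: emitting the prior for
every conceivable pair would connect the entire gene graph.

## Module detection

S_exp and S_fun are fused by AND (product, the default), OR
(complement-product) or + (sum). Edges are materialised only for
S_final > 0, so under AND the absence of any functional evidence removes the
edge. Clustering defaults to Leiden with the RB-configuration quality at
resolution 4 and an explicit seed (default 0); Louvain and Infomap are
exposed unmodified — Infomap in particular tends to find few, large
clusters on these dense weighted graphs. AMI uses the arithmetic-mean
normalization. Partitions are screened by three structural criteria
(non-singlet fraction > 0.85, < 150 modules, largest module < 150) and
`grid_select` ranks eligible (metric, logic, algorithm, resolution)
configurations by AMI against a reference partition, ties broken by fewer
modules. Manual curation is supported only as a curated-edits table
(gene → new module) that is re-applied verbatim; the tool makes no curation
decisions.

## Temporal dynamics

Each gene's profile is fitted with three nested temporal models: flat
(1 parameter), sigmoid (4) and the double-sigmoid impulse (7, with
`t2 = t1 + Δ, Δ ≥ 0` enforcing onset ≤ offset). Fitting is bounded
trust-region least squares with multi-start: a data-driven initialisation
plus random restarts (8 by default) seeded deterministically from a CRC32
hash of the gene name, optionally mixed with a user seed, and cut short once
residuals reach numerical noise. A more complex model is kept only when it
improves the residual sum of squares by more than 5% per extra parameter
pair, so the flat residual is never beaten by a worse fit. A gene is "on"
where the fitted curve is at or above `level_fraction` (default 0.5) of its
rise amplitude within the trajectory span; a monotone rising fit is on
through the trajectory end. Both the threshold-crossing interval and the raw
(t1, t2) parameters are exported — on noiseless dense profiles they agree,
and the parameterisation is shared with the synthetic generator so recovery
tests are self-consistent. Modules are ordered by mean member onset;
activity is the fraction of member genes on per bin; all-flat modules sort
last with a warning.

## Target inference

The design matrix holds an intercept, one column per TF (log2 normalized
expression, forced to 0 in conditions where that TF was mutated or
CRISPR-targeted), an injection covariate (0 uninjected, 1 single-gene
gRNAs, 1.5 multi-gene gRNAs — derived from the knockout count and
overridable for mis-expression samples) and a numeric batch covariate.
Fitting is iteratively reweighted M-estimation with Andrew's wave
(a = 1.339, its standard tuning constant), MAD scale, coefficient-change
convergence at 1e-8 within 50 iterations; non-converged fits are flagged and
excluded from calls. p-values are the per-coefficient asymptotic normal
tests of the robust fit, uncorrected, matching the fixed p < 1e-9 cutoff.
R² = 1 − SSres/SStot is computed from raw (unweighted) residuals; a constant
response (SStot = 0) is defined as R² = 0 and can never be a target.
Rank-deficient columns (e.g. a TF zeroed everywhere) are dropped with a
warning and reported as NaN. Response genes are restricted to those detected
in ≥1 % of the cell type's cells. Positive and negative targets are called
symmetrically (R² > 0.15, |coef| > 0.05, p < 1e-9, in raw log2-normalized
TF units); induced targets additionally require a positive call in at least
two cell types; classification splits two programs' targets into shared /
A-specific / B-specific using each gene's preferred cell type, with
remainder reported as unclassified.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of `SimulationConfig` (one seed drives
everything), with negative-binomial count noise (dispersion r; `inf` with
`noise_sd = 0` is the deterministic noise-free limit) and optional lognormal
mean noise.

**Trajectory data.** Module genes follow impulse curves with module-shared
onsets spread over [0.05, 0.80], on-width 0.18 in pseudotime, per-gene
timing jitter (sd 0.02), near-zero late plateaus and steep slopes — i.e.
temporally compact pulses, the regime in which distinct waves of remodeling
are distinguishable at all. A background cell population three times the
trajectory's size expresses only the flat background genes; the excess
matters because a marker's AUCPR ratio is bounded by 1/prevalence, so a 2×
fold criterion is only attainable when group cells are a minority of each
pseudotime window, as they are in an embryo.

**Annotations and interactions.** One leaf term per module at depth 2 under
a common root (distinct leaves share only the root, semantic similarity
≈ 0.26 < prior — mirroring how unrelated processes sit far apart in a real
ontology; a flat one-level ontology would make every annotated pair similar
at 0.44 > prior and erase the functional signal). Each gene is annotated in
each of two databases with probability `annotation_coverage` (0.6 — partial,
as real multi-database coverage is) and with its own module's term with
probability `annotation_purity` (0.9), else a distractor term.
Within-module interaction evidence is strong (an experiments channel at
0.8–0.98 with probability 0.9, coexpression at 0.6–0.9 with probability
0.6), with sparse weak cross-module noise links. Confounders: the
co-expressed pair shares exact timing with disjoint terms and no
cross-module interactions; the co-functional pair shares one term but sits
at well-separated onsets.

**Perturbation data.** Target genes respond linearly in log2 space to their
TF's level (coefficient ± effect_size·U(0.8, 1.2), ~25 % negative, with
extra baseline headroom for repressed genes so responses are not clipped at
zero); every gene also carries injection and batch offsets (sd 0.15) as real
confounds the design must absorb. TF levels are N(5, 0.8) clipped at 0,
exactly 0 under knockout. An `outlier_frac` of cells carries gross additive
outliers (+7 log2 on a random quarter of response genes); 50 housekeeping
genes buffer library totals so that outlier cells do not turn into a global
compositional artifact — the failure mode that per-cell QC removes in real
pipelines. Not emulated: ambient RNA, doublets, library-size confounding,
trajectory inference itself.

**What passing tests show.** Recovery at the stated thresholds on these
conditions demonstrates internal consistency — the estimators recover the
generative process they assume — plus robustness to the planted confounders
and contamination. It does not certify performance on real data, where
dynamics are not exact impulses, annotation errors are structured rather
than uniform, and trajectory/pseudotime estimation contributes its own
error.

## Problem sizes

The benchmark suite uses 10 modules × 20 genes + 200 background genes with
1000 trajectory + 3000 background cells for marker and module recovery, a 6
module × 10 gene cascade with 600 cells for temporal ordering, and 200
response genes (40 targets, 2 TFs, 4 conditions × 300 cells) for target
inference — sizes at which every stage's behaviour is already asymptotic
while the full pipeline runs in about a minute.

## Known limitations

- The prior-correction formula floors every evidenced pair at p = 0.41, so
  S_fun is never sparse among annotated genes; the AND fusion (and the
  resolution-4 screening criteria) are what keep the graph clusterable.
- Wang similarity treats relation weights as fixed constants; no
  information-content measures are provided.
- The impulse family cannot represent multi-peaked dynamics; such genes are
  absorbed as whichever single pulse fits best.
- Robust regression protects against gross outliers, not against
  measurement attenuation: coefficients on noisily measured TFs are biased
  toward zero in both the robust and least-squares fits.
- Protein↔gene identifier mapping must happen upstream; STRING-style input
  is expected pre-mapped.
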