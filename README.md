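# mimir

Temporally resolved functional gene modules from developmental scRNA-seq
trajectories — plus robust-regression inference of transcription-factor
target genes from perturbation scRNA-seq.

## The problem

During differentiation, a cell type remodels itself through waves of
coordinated gene expression: fate specification, adhesion and cytoskeleton
changes, expansion of the secretory machinery, and finally cargo production
(collagens in the zebrafish notochord, hatching enzymes in the hatching
gland). Co-expression alone cannot resolve these programs — genes with
unrelated functions peak at the same pseudotime, and genes in the same
pathway can act at different times. `mimir` identifies **gene modules** that
are simultaneously co-expressed *and* co-annotated, orders them along
pseudotime, and tests which TFs drive them.

## The model

For each pair of trajectory-enriched genes *i, j*:

- **Expression similarity** `S_exp = 1 − d′`, where `d′` is the
  Jensen–Shannon divergence (base-2, on sum-normalized gene-by-pseudotime
  profiles) rescaled to `[0, 0.95]` (zero-preserving, so identical dynamics
  keep `S_exp = 1`). Euclidean, cosine and Canberra are available.
- **Functional similarity** combines evidence channels — protein-interaction
  channels (STRING-style, with the opaque `database` channels dropped) and
  one semantic channel per annotation database (Wang term similarity,
  best-match-average over the genes' term sets) — under a fixed prior
  *p* = 0.41:

  `S_fun = 1 − (1 − p) · Π_i (1 − s_i′)`,  `s_i′ = max(0, (S_i − p)/(1 − p))`.

- **Fusion**: `S_final = S_exp · S_fun` (the AND logic; OR and + are
  provided). The weighted gene graph is clustered with **Leiden** optimising
  the Reichardt–Bornholdt configuration quality at resolution 4; partitions
  are screened (>85 % of genes in non-singlet modules, <150 modules, largest
  module <150 genes) and scored against a reference with **adjusted mutual
  information** (AMI).

Upstream, trajectory-enriched genes are called per pseudotime segment (15
equal segments, fused to ≥60 cells) by **AUCPR**: detected in ≥10 % of group
cells, AUCPR ≥2× (trajectory) or ≥7.5× (stage) the uninformative baseline,
log2 fold change >0.3; enriched = marker of the final segment or of ≥2
segments (trajectory), or of any stage. Downstream, each gene's temporal
profile is fitted with a double-sigmoid **impulse model**

`y(t) = (1/h1)·[h0 + (h1−h0)σ(b1(t−t1))]·[h2 + (h1−h2)σ(b2(t2−t))]`

and modules are ordered by the mean onset of their members. TF targets are
inferred per cell type by **robust linear regression** (statsmodels RLM with
Andrew's wave, a = 1.339): gene ≈ baseline + Σ coef·TF + injection + batch,
with knocked-out TFs zeroed, injection ∈ {0, 1, 1.5} and batch ∈ {0, 1};
targets require R² > 0.15, |coef| > 0.05, p < 1e-9, and induced
(mis-expression) targets a positive call in ≥2 cell types.

## Worked example

Everything below runs on synthetic data with planted ground truth — no
downloads. The generator plants 10 impulse-timed modules (20 genes each, 200
flat background genes) with two deliberate confounders: one module pair is
co-expressed but functionally distinct, another shares annotations but is
temporally separated.

```python
import mimir

cfg = mimir.SimulationConfig(seed=0, noise_sd=0.05, dispersion=50.0,
                             confounder_mode="both")
counts, truth = mimir.simulate_trajectory_dataset(cfg)
ontology, annotations, interactions = mimir.simulate_annotations(cfg, truth)

norm = mimir.normalize_counts(counts)                      # 15,000 / +1 / log2
meta = norm.cell_meta
traj = list(meta.index[meta.cell_type == "trajectory"])
segments = mimir.segment_pseudotime(meta.loc[traj, "pseudotime"].astype(float))

genes = sorted(truth.true_partition)
profile = mimir.build_profiles(norm.subset_cells(traj), segments, genes,
                               exclude_presegment=True)
evidence = mimir.assemble_channels(interactions, annotations, ontology, genes=genes)

model = mimir.GeneModuleModel.from_profiles(profile, evidence, metric="jsd", logic="and")
results = model.fit(algorithm="leiden", resolution=4.0, seed=0)
print(results.summary())
print("AMI vs planted modules:", round(results.evaluate(truth.true_partition).ami, 3))
```

prints

```
Gene module detection results
=============================
logic:                and
algorithm:            leiden
resolution:           4.0
seed:                 0
genes:                200
modules:              30
non-singlet fraction: 0.900 (criterion > 0.85: True)
largest module:       20 (criterion < 150: True)
AMI vs planted modules: 0.903
```

The fused similarity recovers the planted partition (AMI 0.90) where
clustering the expression or functional similarity alone does not (AMI 0.01
and 0.34 on the same data): neither source can split both confounded module
pairs, but their product can. The same objects feed the other stages:
`mimir.fit_impulse` + `mimir.order_modules` reconstruct the module cascade,
and `mimir.TargetRegressionModel(...).fit().call_targets()` recovers planted
TF targets from simulated crispant data.

A thin CLI mirrors the library:
`mimir simulate | convert | normalize | enrich | simexp | simfun | modules |
order | targets` (see `mimir --help`).

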