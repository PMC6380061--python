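# prognet

Prognostic gene-module discovery from co-expression **module networks**,
with GeneRank prioritization and survival evaluation.

## The problem

Single-gene prognostic signatures for cancer generalize poorly across
cohorts: genes correlated with survival in one data set are often
passengers in another. Sets of co-expressed genes (modules) are more
stable, but module-selection methods usually treat modules in isolation and
ignore the *cross-talk* between them — a module that is both prognostic and
central to the module interaction structure is a better candidate than an
equally prognostic but isolated one.

`prognet` implements a pipeline that combines both signals:

1. **Co-expression network** — Pearson correlations between all gene pairs;
   each gene is linked to its *k* = 10 most correlated partners (rank-based,
   not threshold-based, so weakly but coherently co-expressed pathways are
   kept). Scale-free quality control fits log₁₀ N(d) ~ log₁₀ d.
2. **Dense modules** — an MCODE-style algorithm (vertex weight = highest
   k-core of the closed neighborhood × core density; greedy seed growth;
   2-core haircut) detects vertex-disjoint clusters; modules with fewer than
   5 genes are discarded.
3. **Module network** — for every module pair, the number of co-expression
   edges running between them is compared with the counts for 1000 random
   gene-set pairs of the same sizes; pairs with permutation p < 0.05 become
   module-network edges.
4. **Prognostic priors** — each module is summarized per patient by the mean
   expression of its genes, s = (Σᵢ eᵢ)/n. A univariate Cox
   proportional-hazards model of survival on s is refit on 400 random 90%
   subsets of the training cohort; the fraction of resamples with p < 0.05
   is the module's prior importance p_j, and the mean coefficient gives its
   effect direction.
5. **GeneRank** — importance is propagated over the module network:
   r_j = (1 − d) p_j + d Σᵢ w_ij r_i / degreeᵢ, with damping d = 0.70,
   solved directly as (I − d WᵀD⁻¹) r = (1 − d) p. The top 5% of modules
   (round-half-up, at least one) are the prognostic modules.
6. **Evaluation** — patients in a new cohort are scored by
   Risk Score = Σ s_i − Σ s_j (positive- minus negative-coefficient
   modules), split into equal high/low-risk groups, and compared by the
   log-rank test and hazard ratio. Performance across cohorts aggregates as
   Dscore = −Σ log₁₀(p-valueᵢ). Baselines: resampling-only "control"
   modules and a random-gene-set permutation test. Hypergeometric
   enrichment tests the selected genes against annotation lists (cancer
   genes, drug targets, gene-age classes).

A synthetic-data generator plants co-expressed modules whose latent
activity drives an exponential survival hazard, so the whole chain is
testable without any cohort downloads.

## Worked example

```python
from prognet import PrognosticModuleModel
from prognet.simulate import SyntheticConfig, generate

cfg = SyntheticConfig(seed=0, n_samples=800)   # 500 train + 300 held-out
expr, clin, truth = generate(cfg)
train, test = expr.sample_ids[:500], expr.sample_ids[500:]

model = PrognosticModuleModel(expr.subset_samples(train), clin.subset(train), seed=0)
results = model.fit()
print(results.summary())
```

```text
Prognostic module network analysis
==================================================
genes x samples          1000 x 500
co-expression network    1000 nodes, 6230 edges (10000 selections)
mean neighbors           12.46
power-law degree fit     correlation 0.997, R^2 0.977
modules (size >= 5)        14
module-network edges     2 (alpha 0.05, 1000 permutations)
Cox resampling           400 reps on 90% of samples
GeneRank damping d       0.7
selected modules         [5]
control modules          [5]

top of ranking:
           generank  rank  selected  sig_frequency  mean_coefficient
module_id
5            0.5882     1      True            400            0.6862
14           0.4118     2     False              0           -0.0711
3            0.3000     3     False            400            0.5741
...
```

Module 5 was significant in all 400 Cox resamples *and* sits in the module
network, so GeneRank ranks it first (0.59 > the 0.30 = (1 − d)·1 an
isolated, always-significant module would get). Note module 14: never
significant on its own, yet ranked second purely through its cross-talk
with module 5 — the network effect the method is built around.

```python
assessment = results.evaluate(expr.subset_samples(test), clin.subset(test))
print(f"held-out: log-rank p = {assessment.logrank_p:.3g}, HR = {assessment.hazard_ratio:.2f}")
```

```text
held-out: log-rank p = 9.87e-10, HR = 2.31
```

The selected module's risk score splits the 300 held-out patients into
groups whose survival differs strongly (hazard ratio 2.31).

The same pipeline is available stage-by-stage from the shell:

```bash
prognet simulate --outdir run --seed 3
prognet network --outdir run
prognet modules --outdir run
prognet modnet  --outdir run --seed 3
prognet profile --outdir run --seed 3
prognet rank    --outdir run
prognet evaluate --outdir run --dataset train:run/expression.tsv:run/clinical.tsv
# or: prognet all --outdir run --seed 3
```

Real cohorts enter through `--expression/--clinical` (TSV/CSV; genes ×
samples with a header row of sample IDs; clinical columns
`sample,time,event`), with optional probe-to-gene averaging via
`--probe-map`.

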