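# metamodule

Meta-analytic discovery of prognostic genes and seed-gene co-expression
modules across independent tumor expression cohorts, with downstream
signature-activation scoring and connectivity-map-style drug-reversal query
export.

## The problem

Recurrently amplified chromosomal regions (such as the long arm of
chromosome 1 in breast cancer) contain hundreds of genes, and single-cohort
survival analyses of their expression are noisy and platform-dependent.
A robust way to find the few genes that actually matter clinically is to
screen **every gene of the locus in several independent cohorts** and demand
consistency: per-cohort evidence in most cohorts *and* a significant pooled
effect.  Once a candidate (seed) gene is found, the genes tightly
co-expressed with it across cohorts form a *module* whose average expression
is a stronger stratifier than any single gene, and whose transcriptional
consequences can be matched against drug perturbation profiles to nominate
reversing compounds.

`metamodule` implements that workflow end-to-end for anyone with per-cohort
genes×samples expression matrices and survival annotations — plus a
synthetic multi-cohort generator with planted ground truth, so the whole
pipeline is testable without downloading a single array.

## The statistics

**Survival screen.** In cohort *k*, gene *g* enters a univariate Cox
proportional-hazards model with expression standardised within cohort, so
β̂_gk is a log hazard ratio per SD with standard error se_gk (Wald
p from β̂/se; Efron handling of tied event times).  Per-cohort estimates are
pooled by DerSimonian–Laird inverse-variance random effects:

    w_k  = 1/se_k²,    β_F = Σw_kβ_k / Σw_k,     Q = Σw_k(β_k − β_F)²
    τ²   = max(0, (Q − (K−1)) / (Σw − Σw²/Σw))
    w*_k = 1/(se_k² + τ²),   β_RE = Σw*β/Σw*,    se_RE = (Σw*)^(−1/2)

with combined p = 2Φ(−|β_RE/se_RE|) and pooled HR = exp(β_RE).  A gene
passes the consistency cascade when its per-cohort Wald p < 0.005 in ≥ 3
cohorts **and** its combined p < 0.005.

**Module derivation.** Per cohort, the Pearson correlation r_k of each gene
with the seed gene is moved to the Fisher scale (z = atanh r, var =
1/(n−3)), pooled with the same DL machinery, and back-transformed; module
members require pooled r ≥ 0.6 (positive) with combined p < 0.001 in ≥ 3
cohorts.  Module expression per sample is the mean over member genes.

**Downstream.** Up/down-tag signatures are scored as mean z(up) − mean
z(down) per sample; signature activation is regressed on seed expression;
gene-set overlaps use the hypergeometric tail P(X ≥ k).  The seed-high
(> 60th percentile) vs seed-low (< 10th percentile) Welch-t contrast is
exported as capped up/down GRP lists, and a rank-based score in [−2, 2]
quantifies whether a perturbation profile reverses (negative) or mimics
(positive) the query.

## Worked example

```python
import numpy as np
from metamodule import (SimConfig, simulate_cohorts, cox_per_gene, pool_dl,
                        define_module, km_stratify, module_score)

config = SimConfig(
    n_cohorts=4, samples_per_cohort=[200, 250, 180, 220],
    n_genes=500, module_size=25, module_loading=np.sqrt(0.7),
    prognostic_genes={"G0001": 0.5}, noise_sd=[1.0, 0.9, 1.1, 1.0], seed=42,
)
bundles = simulate_cohorts(config)

meta = pool_dl([cox_per_gene(b, "G0001") for b in bundles])
print(f"pooled HR = {meta.hr:.3f}  (combined p = {meta.p_combined:.2e}, ...)")

module = define_module(bundles, config.seed_gene)
km = km_stratify(bundles[0], module_score(bundles[0], module))
```

Output:

```
pooled HR = 1.675  (combined p = 6.28e-11, tau2 = 0.0165, significant in 4/4 cohorts, passes cascade: True)
module: 24 genes with pooled r >= 0.6 (top member r = 0.729)
module-high vs module-low log-rank p = 1.36e-04
```

Read: the planted seed gene (true log-HR 0.5/SD, i.e. HR ≈ 1.65) is
recovered with a pooled HR of 1.675, negligible between-cohort
heterogeneity, and passes the full cascade; all 24 other planted module
genes (pairwise r = 0.7) clear the module thresholds; and the module's mean
expression separates survival at the median split.

## The analysis pipeline

The numbered scripts under `analysis/` run the full study on a synthetic
six-cohort, 1635-sample design and write their tables under `results/`:

1. `01_simulate_cohorts.py` — generate and fix the cohorts (bulky TSVs go
   to `scratch/cohorts/`).
2. `02_survival_screen.py` — screen the 500 chromosome-arm genes, apply the
   cascade, export the screen table, forest-plot data and uni/multivariate
   covariate models for the top gene.
3. `03_coexpression_module.py` — derive the seed-gene module and evaluate
   its score as a survival stratifier in every cohort.
4. `04_pathway_activation.py` — score signature activation, regress it on
   seed expression, project the activation PCA, test set overlaps.
5. `05_drug_reversal_query.py` — build the stratified contrast, export the
   GRP query and score synthetic reversing/mimicking/random profiles.

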