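# slemod

Module-based transcriptomic analysis of myeloid-cell gene expression in
systemic lupus erythematosus (SLE).

Purified monocyte/macrophage populations from SLE patients carry disease
signatures that bulk blood profiling dilutes: proinflammatory (M1) and
anti-inflammatory (M2) macrophage polarization programs shift with disease
activity, and groups of co-expressed genes track the SLE Disease Activity
Index (SLEDAI).  `slemod` implements the full analysis chain for such
studies as a tested, reusable library:

- **Preprocessing** — low-intensity probe filtering (automated
  histogram-trough detection), merging of vendor and custom probe
  annotations with exclusion of conflicting probes, collapsing duplicate
  probes per gene by interquartile range, and merging of multiple datasets
  with empirical-Bayes location/scale batch adjustment (the ComBat model).
- **Differential expression** — the moderated t-statistic: per-gene
  residual variances s² with d degrees of freedom are shrunk toward a
  prior s₀² with d₀ df estimated by moment matching on log s²
  (digamma/trigamma inversion), giving s̃² = (d₀s₀² + ds²)/(d₀ + d) and
  t = Δ/(s̃·√(1/nₐ + 1/n_b)) on d + d₀ df.  P-values are Benjamini-Hochberg
  adjusted; the DE gate is a deliberately permissive FDR < 0.2.
- **Polarization scoring** — fraction of M1/M2 signature genes upregulated
  per cohort, and fold-change comparison of genes upregulated in both
  active and inactive disease.
- **Co-expression modules** — unsigned weighted network a_ij = |cor|^β with
  β chosen for approximate scale-free topology, topological overlap matrix
  TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
  average-linkage clustering with PAM-style reattachment, eigengene
  merging at dissimilarity 0.2, kME (gene–eigengene correlation) module
  membership, mean-kME quality, and module–trait correlation (Pearson for
  continuous traits, point-biserial for dichotomies).
- **Single-sample enrichment** — a KS-like random walk over genes ranked by
  a rank-based normal-quantile statistic, weighted |z|^τ, yielding
  per-sample, per-gene-set scores in [−1, 1]; chi-squared (1 df) category
  enrichment of DE lists.
- **Disease-activity classification** — elastic-net logistic regression on
  module enrichment scores with cross-validated penalty (1-SE rule),
  ROC/AUC, and per-module odds ratios for active disease,
  OR = (enriched_active × nonenriched_inactive) /
  (nonenriched_active × enriched_inactive), with Haldane–Anscombe
  correction for zero cells.

A synthetic-data generator plants all of this structure — cohorts with
integer SLEDAI scores, co-expression modules whose latent factors are
calibrated to chosen SLEDAI correlations, M1/M2 signature fold-change
patterns, and per-dataset batch offsets — so every stage is testable
against known ground truth without any external downloads.

## Worked example

```python
import slemod as sm

config = sm.SyntheticConfig()          # 40 samples, 2000 genes, 5 planted modules
eset, truth = sm.generate_dataset(config, seed=1)

de = sm.de_workflow(eset, signatures=truth.signature_gene_sets())
for cohort, table in de["tables"].items():
    print(f"{cohort}: {len(table)} DE genes at FDR<0.2")
print(de["polarization"].fractions.to_string(index=False))

mod = sm.module_workflow(eset, power=6)
ms = mod["modules"]
print("modules:", {m: int((ms.assignment == m).sum()) for m in ms.modules})
tc = mod["trait_correlation"].query("trait == 'sledai'")
print(tc[["module", "r", "p"]].round(3).to_string(index=False))
```

prints

```
SLE_inactive: 80 DE genes at FDR<0.2
SLE_active: 222 DE genes at FDR<0.2
signature       cohort  n_signature_in_de  n_up  fraction_up
       M1 SLE_inactive                 13    13          1.0
       M2 SLE_inactive                 28    28          1.0
       M1   SLE_active                 29    29          1.0
       M2   SLE_active                  2     2          1.0
modules: {'turquoise': 113, 'brown': 106, 'blue': 101, 'yellow': 100, 'green': 96}
   module      r     p
turquoise  0.817 0.000
    brown -0.471 0.002
     blue  0.341 0.031
   yellow -0.223 0.166
    green -0.017 0.918
```

More genes reach significance in active than inactive disease; every M1/M2
signature gene that reaches the DE tables is called upregulated (the
generator plants positive shifts for both signatures, strongest for M1 in
active disease); and the five detected modules recover the five planted
ones, with eigengene–SLEDAI correlations close to the configured targets
(0.8, −0.5, 0.35, −0.2, 0).

The estimators behind these workflows (`ModeratedTTest`,
`CoexpressionModules`, `GeneSetScorer`, `EmpiricalBayesBatchCorrector`,
`ActivityClassifier`) follow scikit-learn conventions — `fit`/`transform`/
`predict`, `get_params`/`set_params`, fitted attributes with a trailing
underscore — and compose with sklearn model selection.

A `slemod` command-line tool exposes the same pipeline as subcommands
(`simulate`, `preprocess`, `de`, `modules`, `score`, `classify`,
`report`); every run writes a provenance JSON next to its outputs.

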