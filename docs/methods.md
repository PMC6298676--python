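# Methods

This note documents the statistical models implemented in `slemod`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohorts and preprocessing

Disease activity follows the clinical convention for the SLE Disease
Activity Index: SLEDAI < 6 is inactive, SLEDAI ≥ 6 active; healthy
controls carry no (or zero) SLEDAI.  The cutoff is a fixed constant
(`SLEDAI_ACTIVE_CUTOFF`), and sample metadata validates cohort/SLEDAI
consistency on construction.

**Low-intensity filtering.**  The conventional practice is to cut the
per-probe mean-intensity histogram at the trough between the
background and signal modes, selected by eye.  We automate it: the
threshold is the first interior local minimum of a Gaussian kernel density
estimate (Scott bandwidth, 512-point grid) of the per-probe means.  When
the density has no interior minimum the filter falls back to a quantile
threshold (default q = 0.25) with a warning.  Either way the chosen
threshold and removal counts are appended to the expression set's
provenance log, so a filtered matrix is reproducible from the log alone.

**Annotation merging.**  Two probe→gene maps are merged: probes only the
primary (vendor) source annotates keep it; probes the primary source
misses are rescued from the custom source; probes both sources annotate to
*different* genes are excluded outright.  The case where both sources
agree is not forced by any rule we inherit; we keep the primary source as
the least-surprise choice.  The three resulting classes (primary-kept,
custom-rescued, excluded) partition the probe union and their counts are
reported.

**Probe collapsing.**  Duplicate probes per gene are collapsed by keeping
the probe with the largest interquartile range across samples — the
duplicate with the most biological dynamic range.  Ties break to the
lexicographically smallest probe id so collapsing is order-independent.

**Batch adjustment.**  `merge_datasets` restricts to the gene symbols
shared by all datasets and, when adjustment is on, treats dataset id as
the batch label in a per-gene empirical-Bayes location/scale model: genes
are standardized by their grand mean and pooled within-batch variance;
per-batch additive (γ) and multiplicative (δ²) effects are estimated per
gene and shrunk toward their across-gene batch means using a normal prior
on γ and an inverse-gamma prior on δ², both moment-matched, solved by a
fixed-point iteration of the conditional posterior means (tolerance 1e-8).
This is the standard parametric ComBat model; our implementation agrees
with the reference R implementation elementwise to ~1e-7 on shared
fixtures (the residual gap is the reference's looser convergence
tolerance), and the test suite asserts that agreement through `Rscript`.
Note what the model does *not* promise: with a batch effect common to all
genes, the per-gene location estimates are shrunk almost entirely to the
across-gene mean, so per-gene batch-mean gaps of ~0.1 log2 units can
survive adjustment even though the common offset is removed.  A plain
per-batch standardization mode (`method="standardize"`) is provided for
debugging.

## Moderated differential expression

For a two-group contrast, each gene has Δ = mean_a − mean_b, pooled
residual variance s² on d = n_a + n_b − 2 df.  The empirical-Bayes
hyperparameters (d₀, s₀²) come from moment matching the scaled-F marginal
of the s² on the log scale: Var[log s²] = ψ′(d/2) + ψ′(d₀/2) and
E[log s²] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2), with the
trigamma equation inverted by Newton iteration.  The posterior variance is
s̃² = (d₀s₀² + ds²)/(d₀ + d), the moderated t = Δ/(s̃√(1/n_a + 1/n_b)) is
referred to a t distribution with d + d₀ df (normal when d₀ = ∞, which
occurs when the observed spread of log s² does not exceed its sampling
floor).  Genes with zero residual variance are excluded from hyperparameter
estimation but still get a positive posterior variance.  The implementation
agrees with the R limma `lmFit`/`eBayes` reference to ~1e-14 on shared
fixtures (asserted in the test suite through `Rscript`).

P-values are adjusted with our own Benjamini-Hochberg step-up
(q₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·m/j, capped at 1), tested against both a
literal brute-force evaluation and statsmodels.  The DE gate is *strictly*
FDR < 0.2 — a permissive level that accepts some false positives to avoid
excluding false negatives, appropriate because the downstream module and
enrichment analyses do not depend on an exact FDR.  For probe-level
tables, only the most significant probe per gene is kept (ties to the
smallest probe id).

Contrasts are plain two-group mean differences (each SLE cohort versus
healthy controls) with no covariates.

**Polarization scoring** summarizes a gated DE table against M1/M2
signature lists: fraction of signature genes in the table called
upregulated (genes absent from the table are excluded from the
denominator; empty overlap reports a missing fraction), and for genes
upregulated in both SLE cohorts, δ = lfc_active − lfc_inactive per gene
with an M1/M2/other tag.

## Co-expression modules

The network is unsigned: a_ij = |cor(x_i, x_j)|^β.  Signed networks are a
reasonable alternative; unsigned is the historical default and what
"network strength" denotes here.  β is the smallest candidate power whose
connectivity distribution reaches scale-free fit R² ≥ 0.8 (R² of the
log-log regression of bin frequency on mean bin connectivity over 10
logarithmic bins); if no candidate reaches it, the best-fitting power is
used with a warning.  The topological overlap matrix is
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), TOM_ii = 1,
verified against a literal triple-loop reference.

**Tree cutting.**  Genes are clustered by average linkage on 1 − TOM.  A
fixed-height cut is degenerate here: every merge height is below 1, and
the informative heights depend on the noise level, which is why dynamic
cutting exists.  We use a deterministic simplification of the dynamic
hybrid algorithm: candidate cut heights are the dendrogram merge heights
below `detect_cut` (default 1, i.e. all of them; subsampled to ≤ 80
quantile-spaced heights for large trees).  A cluster at a candidate cut is
*admissible* if it has ≥ `min_size` genes (default 30) and its mean
within-cluster |cor| exceeds 2.5× the null level E|cor| = √(2/π)/√(n−1)
for independent Gaussian profiles — a sample-size-aware co-expression
floor; selection effects inflate chance clusters to roughly 1.5–2× the
null level, so 2.5× sits above them while genuine modules (e.g. loading
0.8 over noise SD 1, within-correlation ≈ 0.39 at the benchmark's n = 40)
clear it.  Each cut is scored by Σ size·(mean within-cluster TOM − matrix
mean off-diagonal TOM) over its admissible clusters — diluting a module
with background genes lowers the score, so the optimum sits at pure tight
clusters — and the best-scoring cut wins, ties going to the lower (finer)
cut.  Over-splitting at a fine cut is repaired downstream by eigengene
merging.

**Refinement.**  With PAM-style reattachment on (default), assigned genes
move to the cluster with the smallest average TOM distance if strictly
closer than their own, and unassigned genes attach to their nearest
cluster when closer than the midpoint between that cluster's internal mean
distance and the matrix-wide mean.  Module pairs whose eigengenes have
dissimilarity 1 − cor < `merge_cut` (default 0.2) are merged iteratively,
closest pair first; the merge pass is idempotent.  Final membership
follows the greatest within-module correlation with the module eigengene:
assigned genes move to their argmax-kME module (ties keep the current
module) and unassigned genes with best kME ≥ 0.5 are recruited; the
reassign/recruit pass iterates to a fixed point (≤ 10 rounds) because
eigengenes sharpen as membership improves.  The 0.5 recruitment threshold
corresponds to p ≈ 0.001 for a null correlation at n = 40, so chance
recruitment of background genes is rare.  Labels are conventional colors
in decreasing module-size order; leftover genes are `unassigned`.

**Eigengenes and quality.**  The module eigengene is the unit-norm first
principal component of the standardized member genes, sign-oriented so its
mean correlation with members is non-negative; its variance-explained
share is validated against a power-iteration reference.  Module quality is
the mean kME of member genes; modules below 0.3 are flagged low-quality
(the concept — an eigengene dominated by a few variable genes — is
standard; the numeric flag is ours).  Across datasets, the grand mean is
the mean of per-dataset mean kMEs.  Module–trait association uses Pearson
correlation for continuous traits and point-biserial (Pearson on the 0/1
coding — an algebraic identity, asserted to 1e-12) for dichotomies, with
two-sided p from t = r√((n−2)/(1−r²)) on n − 2 df.

## Single-sample enrichment

Expression values are reduced per gene to midrank/(n+1) quantiles mapped
through the standard normal quantile function — invariant to any strictly
monotone per-gene transform; constant genes score 0.  For each sample,
genes are ordered by *decreasing statistic* and a weighted KS walk steps
up by |z|^τ (normalized over in-set genes; uniform when all in-set
statistics are 0) at in-set genes and down by 1/(N − |S|) otherwise.
ES⁺/ES⁻ are the maximal positive/negative deviations; the default score is
ES⁺ − ES⁻ (`diff`), with `maxabs` (largest-magnitude deviation, signed)
also available, and τ exposed (default 1).  The signed ordering matters:
it makes the null score distribution symmetric around zero (the |z|^τ
weight profile is symmetric across the two ends of the ranked list), lets
the score distinguish coordinately high from coordinately low set genes,
and makes sign-flipping a sample's statistics negate its diff score —
three properties an ordering by decreasing |z| provably lacks (an
absolute-value ordering gives every random set a positive bias and cannot
tell a +1 SD from a −1 SD shift).  Sets are intersected with the matrix
before scoring (overlap sizes logged); a set covering all genes is an
error, an empty overlap yields missing scores.

Category enrichment of a DE list against a background uses the 2×2
chi-squared statistic with 1 df and no continuity correction, flagged at
p < 0.05; when any expected cell is below 1 the exact (Fisher) test is
substituted and recorded.

## Disease-activity classification

Enrichment scores of module gene lists over the batch-adjusted merged
dataset form the feature matrix (one column per cell-type module; modules
with no gene overlap are dropped with a warning).  The classifier is
logistic regression with an elastic-net penalty, mixing α = 0.5 by default
(the model family is given; the mixing and tuning protocol are ours): the
penalty path runs geometrically from λ_max = max|Xᵀ(y − ȳ)|/(nα) down
three decades, λ is chosen by stratified K-fold (default 5) cross-validated
binomial deviance with the one-standard-error rule, and the final model is
refit on all data.  Features are standardized internally and coefficients
reported on the original scale.  The saga solver's internal shuffling is
pinned, so fits are deterministic given (data, seed).  Held-out
performance is measured by an *outer* stratified K-fold loop whose
per-fold models redo their inner penalty selection; ROC/AUC comes from the
pooled out-of-fold probabilities (trapezoid AUC, equal to pairwise
concordance, asserted against a brute-force count).

Per-module association with active disease uses binary
expected-versus-observed enrichment calls: a sample is enriched when
direction × score > 0, where direction (±1) is the module's expected sign
of activity association (the threshold is exposed; 0 on the signed score
is the natural default).  The odds ratio is
(enriched_active × nonenriched_inactive)/(nonenriched_active ×
enriched_inactive); any zero cell adds 0.5 to every cell
(Haldane–Anscombe, flagged), and the 95% CI uses the log-OR normal
approximation.

## Synthetic data

The generator emulates the study design: x_gs = μ_g + λ_g f_{m(g),s} +
β_{g,cohort(s)} + ε_gs with ε ~ N(0, noise_sd²), μ_g ~ Uniform(5, 10) log2
units.  SLEDAI is integer-valued: 0 for controls, Uniform{0..5} for
inactive, Uniform{6..20} for active patients.  Module factors are tied to
SLEDAI through a Gaussian copula on the SLEDAI midranks, with the residual
orthogonalized in-sample against both the normal scores and the raw trait
and the copula correlation inflated by 1/cor(scores, trait), so each
factor's *sample* correlation with SLEDAI equals its configured target
exactly — including targets of zero, whose factors are orthogonalized
against the trait (an unconstrained Gaussian draw can correlate ±0.2 with
the trait at n = 40, which would contaminate null modules).  Cohort
effects are additive mean shifts on signature genes, the simplest
mechanism that reproduces the observed ordering: by default M1 genes are
up in both SLE cohorts (+2.0 active, +1.0 inactive log2 units) and M2
genes up with the opposite ordering (+0.3 active, +1.5 inactive).
Multi-dataset collections share gene symbols and planted structure, draw
independent samples per dataset, and add an independent per-gene batch
offset ~ N(0, batch_shift_sd²).  Everything is bit-reproducible from
(config, seed); child dataset seeds are spawned from a `SeedSequence`.

Default study conditions: 40 samples (14 HC / 13 inactive / 13 active),
2000 genes, five 100-gene modules with factor loading 0.8, 30 M1 and 30 M2
signature genes, noise SD 1.0, three datasets with batch-offset SD 1.0.
The default module trait-correlation targets are deliberately spread
(0.8, −0.5, 0.35, −0.2, 0): every factor correlates with SLEDAI through
the same copula image of the trait, so two targets of ±0.8 would force
cor(f₁, f₂) ≈ −0.72 — making the two "modules" one co-expression unit in
an unsigned network and the planted truth inconsistent with its own module
structure.  With the spread targets the worst inter-factor correlation is
≈ 0.4, which β = 6 suppresses by two orders of magnitude in adjacency.

The disease-activity scenario (`activity_scenario`) plants one
activity-linked module (trait correlation 0.8) whose first half also
carries the M1-style cohort shifts — mirroring an M1-dominated activity
module, where the activity signal is both co-expression and mean shift —
plus three null modules, across three datasets of 1000 genes.  The
`with_effects=False` variant zeroes the trait link and the cohort shifts
while keeping the module structure, as a negative control.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: probe-level structure with multiple probes
per gene (a dedicated small fixture covers collapsing), mean–variance
trends and heavy-tailed noise of real microarrays, nested or overlapping
modules, correlated signature genes beyond the shared cohort shift,
platform-specific probe behavior, and non-additive batch effects.  The
benchmarks show the estimators recover the structure they model, at
realistic sizes, not that the model captures everything in real arrays.

## Benchmark conditions and numerical choices

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) run, at sizes chosen to keep the whole suite
in a few minutes on one core:

- Null FDR calibration: 100 complete-null replicates of 2000 genes at
  10 vs 10; mean realized false-discovery proportion at the FDR < 0.2 gate.
- DE sensitivity: 100 of 2000 genes shifted by 1.5 noise SDs, 20
  replicates.
- Module recovery: the default five-module conditions above,
  modules-only (no signature genes, which would legitimately co-express
  with the trait-linked factor and confound the ARI against a truth that
  labels them `none`); reports ARI, argmax-kME hit fraction and worst
  trait-correlation error.
- Enrichment: a 1-SD coordinated shift of a 50-gene set in half of 200
  samples (detection AUC) and 20 random 50-gene sets on null data (mean
  score).
- Category test: 500 null 2×2 replicates over a 500-gene background.
- Classifier: 20 seeded replicates of the activity scenario (mean held-out
  AUC, fraction of replicates where the linked module's OR tops all null
  modules), 20 label permutations, and 5 no-effect replicates.
- Oracle equivalences (BH step-up, TOM triple loop, eigengene power
  iteration, point-biserial identity, OR formula over all 2×2 tables with
  cells ≤ 10) and a double-run determinism digest of a small end-to-end
  pipeline.

Numerical details worth knowing: correlations are clipped to [−1, 1]
before powering; TOM is symmetrized and clipped to [0, 1]; trigamma
inversion runs Newton iterations to relative 1e-10; the batch-effect
fixed point iterates to 1e-8; rank ties use midranks everywhere;
empty-overlap gene sets propagate missing scores rather than zeros; and
all ordering-dependent steps (probe ties, kME ties, label assignment,
merge order) have deterministic tie-breaks.

## Known limitations

Static candidate-cut scanning with a co-expression admission floor is
simpler than the full dynamic hybrid tree cut and can miss modules whose
within-module correlation sits near the floor (≈ 0.32 at n = 40);
lowering the admission factor trades that against chance clusters.  The
unsigned network cannot separate modules whose factors are strongly
mutually correlated (they are genuinely one co-expression unit under
|cor|).  The elastic-net tuning protocol (α = 0.5, 1-SE rule) is a
convention, not an inherited choice.  Consensus modules across datasets,
module preservation statistics, probe-level simulation and multi-factor
DE designs are out of scope.
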