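"""Benchmark experiments on synthetic data with planted ground truth.

Each function runs one calibration or recovery experiment under the
package's study conditions and returns summary metrics.  They are used by
the acceptance script and the test suite, and are convenient for checking
an installation end to end.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .activity import cross_validated_scores, odds_ratio_active, call_enrichment
from .data import GeneSetCollection
from .diffexp import ModeratedTTest, adjust_bh
from .enrich import category_enrichment, gene_level_stats, score_gene_sets
from .modules import UNASSIGNED
from .simulate import (
    SyntheticConfig,
    activity_scenario,
    generate_activity_collection,
    generate_dataset,
)
from .workflows import activity_workflow, module_workflow

__all__ = [
    "fdr_null_calibration",
    "de_power",
    "module_recovery",
    "enrichment_detection",
    "category_null_calibration",
    "classifier_recovery",
    "pipeline_digest",
]


def _moderated_discoveries(X: np.ndarray, n_a: int, fdr_cut: float = 0.2) -> np.ndarray:
    """Boolean discovery vector from a moderated-t two-group comparison."""
    y = np.array(["a"] * n_a + ["b"] * (X.shape[1] - n_a))
    est = ModeratedTTest(baseline="b").fit(X.T, y)
    return est.fdr_ < fdr_cut


def fdr_null_calibration(
    seed: int, n_reps: int = 100, n_genes: int = 2000, n_per_group: int = 10
) -> dict:
    """Mean realized false-discovery proportion under the complete null.

    Every discovery at FDR < 0.2 is false, so each replicate's FDP is 1 if
    anything is discovered and 0 otherwise; the mean over replicates
    estimates E[FDP], which Benjamini-Hochberg controls at the gate level.
    """
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_reps):
        X = rng.standard_normal((n_genes, 2 * n_per_group))
        hits = _moderated_discoveries(X, n_per_group)
        fdps.append(1.0 if hits.any() else 0.0)
    return {"mean_fdp": float(np.mean(fdps)), "n": n_reps}


def de_power(
    seed: int,
    n_reps: int = 20,
    n_genes: int = 2000,
    n_shifted: int = 100,
    shift_in_sd: float = 1.5,
    n_per_group: int = 10,
) -> dict:
    """Sensitivity for genes shifted by ``shift_in_sd`` noise SDs at FDR < 0.2."""
    rng = np.random.default_rng(seed)
    sens = []
    for _ in range(n_reps):
        X = rng.standard_normal((n_genes, 2 * n_per_group))
        X[:n_shifted, :n_per_group] += shift_in_sd
        hits = _moderated_discoveries(X, n_per_group)
        sens.append(hits[:n_shifted].mean())
    return {"sensitivity": float(np.mean(sens)), "n": n_reps}


def module_recovery(seed: int, power: float = 6.0) -> dict:
    """Recovery of five planted 100-gene modules among 2000 genes (n = 40).

    Modules-only study conditions (factor loading 0.8, noise SD 1); reports
    assignment ARI against the planted truth, the fraction of planted genes
    whose argmax kME is their true module, and the worst absolute error of
    the recovered module-SLEDAI correlations versus the configured targets.
    """
    cfg = SyntheticConfig(m1_genes=0, m2_genes=0)
    eset, truth = generate_dataset(cfg, seed=seed)
    result = module_workflow(eset, power=power)
    ms = result["modules"]
    truth_labels = pd.Series(
        [truth.module_of_gene[g] or UNASSIGNED for g in eset.row_ids], index=eset.row_ids
    )
    ari = adjusted_rand_score(truth_labels.to_numpy(), ms.assignment.to_numpy())

    planted = truth_labels != UNASSIGNED
    mapping = {}
    for tm in truth_labels[planted].unique():
        counts = ms.assignment[truth_labels == tm].value_counts()
        counts = counts[counts.index != UNASSIGNED]
        mapping[tm] = counts.idxmax() if len(counts) else None
    hits = sum(
        mapping[truth_labels[g]] is not None
        and ms.kme.loc[g].idxmax() == mapping[truth_labels[g]]
        for g in truth_labels.index[planted]
    )
    kme_frac = hits / int(planted.sum())

    tc = result["trait_correlation"].query("trait == 'sledai'").set_index("module")["r"]
    targets = {f"module_{k + 1}": spec.trait_corr for k, spec in enumerate(cfg.modules)}
    errs = [
        abs(abs(tc.get(mapping[tm], 0.0)) - abs(target)) for tm, target in targets.items()
    ]
    return {
        "ari": float(ari),
        "kme_argmax_fraction": float(kme_frac),
        "max_trait_corr_error": float(max(errs)),
        "n": cfg.n_genes,
    }


def enrichment_detection(
    seed: int,
    n_genes: int = 1000,
    set_size: int = 50,
    n_samples: int = 200,
    shift: float = 1.0,
    n_null_sets: int = 20,
) -> dict:
    """Planted coordinated shift of a gene set in half the samples.

    Reports the AUC of the single-sample score for separating shifted from
    unshifted samples, and the mean score of random sets on null data.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_genes, n_samples))
    members = rng.choice(n_genes, set_size, replace=False)
    genes = [f"G{i}" for i in range(n_genes)]
    shifted = np.arange(n_samples // 2)
    Xs = X.copy()
    Xs[np.ix_(members, shifted)] += shift
    em = score_gene_sets(
        gene_level_stats(pd.DataFrame(Xs, index=genes)),
        GeneSetCollection({"planted": [genes[i] for i in members]}),
    )
    y = np.zeros(n_samples)
    y[shifted] = 1
    auc = roc_auc_score(y, em.scores["planted"].to_numpy())

    null_sets = GeneSetCollection(
        {
            f"S{j}": [genes[i] for i in rng.choice(n_genes, set_size, replace=False)]
            for j in range(n_null_sets)
        }
    )
    null = score_gene_sets(gene_level_stats(pd.DataFrame(X, index=genes)), null_sets)
    return {
        "auc": float(auc),
        "null_mean_score": float(null.scores.to_numpy().mean()),
        "n": n_samples,
    }


def category_null_calibration(
    seed: int, n_reps: int = 500, n_background: int = 500, n_de: int = 100, n_cat: int = 80
) -> dict:
    """Type-I rate of the chi-squared category test with DE lists drawn
    independently of the categories."""
    rng = np.random.default_rng(seed)
    background = [f"g{i}" for i in range(n_background)]
    flags = 0
    for _ in range(n_reps):
        de = list(rng.choice(background, n_de, replace=False))
        cat = list(rng.choice(background, n_cat, replace=False))
        out = category_enrichment(de, background, GeneSetCollection({"c": cat}))
        flags += int(out.table["significant"].iloc[0])
    return {"flag_rate": flags / n_reps, "n": n_reps}


def classifier_recovery(seed: int, n_seeds: int = 20, n_permutations: int = 20) -> dict:
    """Disease-activity classification across a 3-dataset collection.

    One activity-linked module (trait correlation 0.8, M1-style cohort
    shifts on half its genes) among null modules.  Reports the mean
    held-out AUC over ``n_seeds`` replicates, how often the linked module's
    odds ratio tops every null module's, the mean label-permutation AUC,
    and the mean AUC with all activity effects removed.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_seeds)]
    cfg = activity_scenario()
    aucs, or_top = [], 0
    first = None
    for rs in rep_seeds:
        coll = generate_activity_collection(cfg, seed=rs)
        res = activity_workflow(
            [e for e, _ in coll], coll[0][1].module_gene_sets(), seed=rs
        )
        aucs.append(res["roc"].auc)
        ors = res["odds_ratios"].table["or"]
        if ors["module_1"] > ors.drop("module_1").max():
            or_top += 1
        if first is None:
            first = res

    # permutation null on the first replicate's features
    merged = first["merged"]
    sle_ids = [s for s, c in zip(merged.sample_ids, merged.cohorts) if c != "HC"]
    feats = first["features"].scores.loc[sle_ids]
    y = first["labels"]
    perm_aucs = []
    for rep in range(n_permutations):
        rng = np.random.default_rng(rep_seeds[0] + rep + 1)
        yp = rng.permutation(y)
        sc = cross_validated_scores(feats, yp, seed=rep)
        perm_aucs.append(roc_auc_score(yp, sc))

    # negative control: same design, activity effects removed
    cfg0 = activity_scenario(with_effects=False)
    null_aucs = []
    for rs in rep_seeds[:5]:
        coll0 = generate_activity_collection(cfg0, seed=rs)
        res0 = activity_workflow(
            [e for e, _ in coll0], coll0[0][1].module_gene_sets(), seed=rs
        )
        null_aucs.append(res0["roc"].auc)
    return {
        "mean_heldout_auc": float(np.mean(aucs)),
        "min_heldout_auc": float(np.min(aucs)),
        "or_top_fraction": or_top / n_seeds,
        "mean_permutation_auc": float(np.mean(perm_aucs)),
        "mean_no_effect_auc": float(np.mean(null_aucs)),
        "n": n_seeds,
    }


def pipeline_digest(seed: int) -> str:
    """SHA-256 digest of every stage's output on a small end-to-end run.

    Two calls with the same seed must return identical digests.
    """
    from .simulate import ModuleSpec

    cfg = SyntheticConfig(
        n_genes=400,
        modules=[ModuleSpec(size=60, trait_corr=0.7), ModuleSpec(size=60, trait_corr=0.0)],
    )
    eset, truth = generate_dataset(cfg, seed=seed)
    h = hashlib.sha256()
    h.update(eset.values.to_numpy().tobytes())

    from .workflows import de_workflow

    de = de_workflow(eset, signatures=truth.signature_gene_sets())
    for cohort in sorted(de["tables"]):
        h.update(de["tables"][cohort].to_csv().encode())

    mod = module_workflow(eset, power=6)
    h.update(mod["modules"].assignment.to_csv().encode())
    h.update(np.ascontiguousarray(mod["modules"].eigengenes.to_numpy()).tobytes())

    em = score_gene_sets(gene_level_stats(eset), truth.module_gene_sets())
    h.update(np.ascontiguousarray(em.scores.to_numpy()).tobytes())

    cfg_act = activity_scenario(n_genes=400, module_size=50, n_null_modules=1)
    coll = generate_activity_collection(cfg_act, seed=seed)
    res = activity_workflow([e for e, _ in coll], coll[0][1].module_gene_sets(), seed=seed)
    h.update(np.ascontiguousarray(res["model"].coef_).tobytes())
    h.update(res["odds_ratios"].table.to_csv().encode())
    return h.hexdigest()
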