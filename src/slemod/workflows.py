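"""End-to-end analysis workflows tying the pipeline stages together.

These are the high-level entry points the CLI uses: differential
expression with polarization scoring, co-expression module discovery with
trait correlation, and disease-activity classification from module
enrichment across merged datasets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activity import (
    build_features,
    call_enrichment,
    cross_validated_scores,
    fit_activity_glm,
    odds_ratio_active,
    roc_auc,
)
from .data import HC, SLE_ACTIVE, SLE_INACTIVE, ExpressionSet, GeneSetCollection
from .diffexp import (
    common_foldchange_compare,
    fit_moderated_t,
    polarization_fraction,
    select_de,
)
from .modules import CoexpressionModules, correlate_module_traits
from .preprocess import merge_datasets

__all__ = ["de_workflow", "module_workflow", "activity_workflow"]


def de_workflow(
    eset: ExpressionSet,
    signatures: GeneSetCollection | None = None,
    fdr_cut: float = 0.2,
) -> dict:
    """Differential expression of each SLE cohort versus healthy controls.

    Returns per-cohort DEResults and gated tables, the M1/M2 polarization
    summary and the common-upregulated fold-change comparison (when both
    SLE cohorts are present and signatures are supplied).
    """
    cohorts = eset.cohorts
    hc_ids = [s for s, c in zip(eset.sample_ids, cohorts) if c == HC]
    if len(hc_ids) < 2:
        raise ValueError("need at least two healthy-control samples")
    out: dict = {"de": {}, "tables": {}}
    for cohort in (SLE_INACTIVE, SLE_ACTIVE):
        ids = [s for s, c in zip(eset.sample_ids, cohorts) if c == cohort]
        if len(ids) < 2:
            continue
        de = fit_moderated_t(eset, ids, hc_ids)
        out["de"][cohort] = de
        out["tables"][cohort] = select_de(de, fdr_cut=fdr_cut)
    if signatures is not None and out["tables"]:
        out["polarization"] = polarization_fraction(out["tables"], signatures)
        if SLE_ACTIVE in out["tables"] and SLE_INACTIVE in out["tables"]:
            out["common_foldchange"] = common_foldchange_compare(
                out["tables"][SLE_ACTIVE], out["tables"][SLE_INACTIVE], signatures
            )
    return out


def module_workflow(
    eset: ExpressionSet,
    power: float | None = None,
    detect_cut: float = 1.0,
    merge_cut: float = 0.2,
    min_size: int = 30,
    traits: pd.DataFrame | None = None,
) -> dict:
    """Co-expression module discovery plus module-trait correlation.

    Default traits are SLEDAI (continuous) and SLE-vs-HC (dichotomous).
    """
    est = CoexpressionModules(
        power=power, detect_cut=detect_cut, merge_cut=merge_cut, min_size=min_size
    ).fit(eset.values.to_numpy().T)
    module_set = est.module_set_
    # rename gene index to the real gene ids (estimator works positionally)
    module_set.assignment.index = eset.row_ids
    module_set.kme.index = eset.row_ids
    module_set.eigengenes.index = pd.Index(eset.sample_ids)
    result = {"modules": module_set, "power": est.power_}
    if module_set.modules:
        if traits is None:
            traits = pd.DataFrame(
                {
                    "sledai": eset.sledai,
                    "sle": (eset.cohorts != HC).astype(float),
                },
                index=pd.Index(eset.sample_ids),
            )
        result["trait_correlation"] = correlate_module_traits(
            module_set, eset.samples, traits
        )
    return result


def activity_workflow(
    esets: list[ExpressionSet],
    module_gene_sets: GeneSetCollection,
    directions: dict[str, int] | None = None,
    alpha: float = 0.5,
    n_folds: int = 5,
    seed: int | None = None,
    tau: float = 1.0,
    mode: str = "diff",
) -> dict:
    """Disease-activity classification from module enrichment.

    Merges the datasets with batch adjustment, scores the module gene sets
    per sample, fits the penalized GLM on active-vs-inactive SLE samples,
    and reports held-out (outer CV) AUC plus per-module odds ratios for
    active disease.  ``directions`` defaults to +1 for every module.
    """
    merged = merge_datasets(esets, adjust=True)
    features = build_features(merged, module_gene_sets, tau=tau, mode=mode)
    cohorts = merged.cohorts
    sle_mask = cohorts != HC
    sle_ids = [s for s, keep in zip(merged.sample_ids, sle_mask) if keep]
    scores = features.scores.loc[sle_ids]
    labels = (cohorts[sle_mask] == SLE_ACTIVE).astype(int)

    model = fit_activity_glm(scores, labels, alpha=alpha, n_folds=n_folds, seed=seed)
    heldout = cross_validated_scores(scores, labels, alpha=alpha, n_folds=n_folds, seed=seed)
    roc = roc_auc(heldout, labels=labels)

    if directions is None:
        directions = {c: 1 for c in scores.columns}
    calls = call_enrichment(scores[list(scores.columns)], directions)
    ors = odds_ratio_active(calls, labels)
    return {
        "merged": merged,
        "features": features,
        "labels": labels,
        "model": model,
        "heldout_scores": heldout,
        "roc": roc,
        "odds_ratios": ors,
    }
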