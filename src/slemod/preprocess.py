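"""Preprocessing of probe-level expression data.

Covers the steps between a normalized log2 matrix and an analysis-ready
gene-level matrix: removal of low-intensity probes, merging of a primary
(vendor) probe annotation with a custom one, collapsing duplicate probes per
gene by interquartile range, and merging multiple datasets with
empirical-Bayes batch adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ExpressionSet, ProbeAnnotation

__all__ = [
    "filter_low_intensity",
    "merge_probe_annotations",
    "collapse_probes_iqr",
    "merge_datasets",
    "EmpiricalBayesBatchCorrector",
]


def _kde_valley(means: np.ndarray, grid_size: int = 512) -> float | None:
    """First interior local minimum of a Gaussian KDE of per-row means.

    Returns None when the density has no interior minimum (unimodal).
    """
    kde = stats.gaussian_kde(means)
    lo, hi = means.min(), means.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] < dens[:-2]) & (dens[1:-1] < dens[2:])) + 1
    if interior.size == 0:
        return None
    return float(grid[interior[0]])


def filter_low_intensity(
    eset: ExpressionSet,
    strategy: str = "valley",
    quantile_q: float = 0.25,
) -> ExpressionSet:
    """Remove probes whose mean log2 intensity falls below a threshold.

    The threshold automates the conventional practice of cutting at the
    trough of the low-intensity mode of the per-probe mean histogram:

    - ``"valley"``: first local minimum of a kernel density estimate of the
      per-row means; when the density is unimodal this falls back to the
      quantile strategy with a warning.
    - ``"quantile"``: the ``quantile_q`` quantile of the per-row means
      (``q=0`` keeps everything).

    The chosen threshold and the number of rows removed are appended to the
    output's provenance log.
    """
    if strategy not in ("valley", "quantile"):
        raise ValueError("strategy must be 'valley' or 'quantile'")
    if not 0 <= quantile_q <= 1:
        raise ValueError("quantile_q must be in [0, 1]")
    means = eset.values.mean(axis=1).to_numpy()
    used = strategy
    threshold = None
    if strategy == "valley":
        threshold = _kde_valley(means)
        if threshold is None:
            warnings.warn(
                "intensity density is unimodal; falling back to quantile threshold",
                stacklevel=2,
            )
            used = "quantile"
    if threshold is None:
        threshold = float(np.quantile(means, quantile_q)) if quantile_q > 0 else -np.inf
    keep = means >= threshold
    out = ExpressionSet(
        eset.values.loc[keep],
        eset.samples,
        row_level=eset.row_level,
        provenance=list(eset.provenance),
    )
    out.log_step(
        "filter_low_intensity",
        strategy=used,
        threshold=None if np.isneginf(threshold) else threshold,
        n_removed=int((~keep).sum()),
        n_kept=int(keep.sum()),
    )
    return out


def merge_probe_annotations(
    primary_map: dict[str, str], custom_map: dict[str, str]
) -> ProbeAnnotation:
    """Merge vendor (primary) and custom probe->gene annotations.

    Rules: probes annotated only by the primary source keep it; probes the
    primary source misses are rescued from the custom source; probes both
    sources annotate to the same gene keep the primary source; probes the
    two sources assign to *different* genes are excluded outright.
    """
    entries: dict[str, tuple[str, str]] = {}
    excluded: set[str] = set()
    n_primary = n_rescued = 0
    for probe, gene in primary_map.items():
        custom_gene = custom_map.get(probe)
        if custom_gene is not None and custom_gene != gene:
            excluded.add(probe)
        else:
            entries[probe] = (gene, "primary")
            n_primary += 1
    for probe, gene in custom_map.items():
        if probe not in primary_map:
            entries[probe] = (gene, "custom")
            n_rescued += 1
    counts = {
        "primary_kept": n_primary,
        "custom_rescued": n_rescued,
        "excluded": len(excluded),
    }
    return ProbeAnnotation(entries=entries, excluded=excluded, counts=counts)


def collapse_probes_iqr(eset: ExpressionSet, annotation: ProbeAnnotation) -> ExpressionSet:
    """Collapse a probe-level set to gene level, keeping one probe per gene.

    For genes measured by several probes, the probe with the largest
    interquartile range across samples is retained (the most informative
    duplicate); ties break to the lexicographically smallest probe id.
    Probes present in the matrix but absent from the annotation raise.
    """
    missing = [p for p in eset.row_ids if p not in annotation.entries]
    if missing:
        raise KeyError(f"probes without annotation: {missing[:5]}")
    iqr = eset.values.quantile(0.75, axis=1) - eset.values.quantile(0.25, axis=1)
    table = pd.DataFrame(
        {
            "probe": eset.row_ids,
            "gene": [annotation.gene_of(p) for p in eset.row_ids],
            "iqr": iqr.to_numpy(),
        }
    )
    # max IQR per gene; ties -> smallest probe id (sort makes idxmax deterministic)
    table = table.sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
    best = table.groupby("gene", sort=True).head(1)
    values = eset.values.loc[best["probe"]].copy()
    values.index = pd.Index(best["gene"], name="gene")
    out = ExpressionSet(
        values,
        eset.samples,
        row_level="gene",
        provenance=list(eset.provenance),
    )
    out.log_step(
        "collapse_probes_iqr",
        n_probes_in=int(eset.n_rows),
        n_genes_out=int(out.n_rows),
    )
    return out


class EmpiricalBayesBatchCorrector(BaseEstimator, TransformerMixin):
    """Per-gene empirical-Bayes location/scale batch adjustment.

    Removes additive and multiplicative batch effects from a log2 expression
    matrix, shrinking per-gene batch effects toward their across-gene means
    (normal prior on the location effect, inverse-gamma on the scale effect,
    both moment-matched), in the spirit of the standard empirical-Bayes
    batch-correction scheme for expression microarrays.

    Parameters
    ----------
    method : {"eb", "standardize"}
        ``"eb"`` applies the shrunken adjustment; ``"standardize"`` is a
        plain per-batch per-gene mean/variance standardization (no
        shrinkage), useful for debugging.
    max_iter, tol
        Fixed-point iteration control for the conditional posterior means of
        the batch effects.

    Notes
    -----
    ``fit``/``transform`` operate on ``X`` with shape (n_samples, n_genes)
    and require the batch label of every sample.  Each batch must contain at
    least two samples.
    """

    def __init__(self, method: str = "eb", max_iter: int = 100, tol: float = 1e-8):
        self.method = method
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, batch):
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        if batch.shape[0] != X.shape[0]:
            raise ValueError("batch must have one label per sample")
        if self.method not in ("eb", "standardize"):
            raise ValueError("method must be 'eb' or 'standardize'")
        self.batches_ = [b for b in dict.fromkeys(batch.tolist())]
        sizes = {b: int((batch == b).sum()) for b in self.batches_}
        small = [b for b, n in sizes.items() if n < 2]
        if small:
            raise ValueError(f"batches with fewer than 2 samples: {small}")
        if len(self.batches_) < 2:
            raise ValueError("need at least two batches")

        n, g = X.shape
        masks = {b: batch == b for b in self.batches_}
        batch_means = np.vstack([X[masks[b]].mean(axis=0) for b in self.batches_])
        weights = np.array([sizes[b] / n for b in self.batches_])
        # grand per-gene location = size-weighted mean of batch means
        self.grand_mean_ = weights @ batch_means
        resid = X - np.vstack([batch_means[self.batches_.index(b)] for b in batch])
        self.pooled_var_ = (resid**2).sum(axis=0) / n
        self.pooled_var_ = np.maximum(self.pooled_var_, 1e-12)
        return self

    def transform(self, X, batch):
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        sd = np.sqrt(self.pooled_var_)
        Z = (X - self.grand_mean_) / sd
        out = np.empty_like(Z)
        for b in self.batches_:
            mask = batch == b
            if not mask.any():
                continue
            Zb = Z[mask]
            nb = Zb.shape[0]
            gamma_hat = Zb.mean(axis=0)  # per-gene additive batch effect
            delta_hat = Zb.var(axis=0, ddof=1)
            delta_hat = np.maximum(delta_hat, 1e-12)
            if self.method == "standardize":
                gamma_star, delta_star = gamma_hat, delta_hat
            else:
                gamma_star, delta_star = self._eb_shrink(Zb, gamma_hat, delta_hat, nb)
            out[mask] = (Zb - gamma_star) / np.sqrt(delta_star)
        return out * sd + self.grand_mean_

    def fit_transform(self, X, batch):  # noqa: D102 - sklearn signature with batch
        return self.fit(X, batch).transform(X, batch)

    def _eb_shrink(self, Zb, gamma_hat, delta_hat, nb):
        # moment-matched priors across genes
        gamma_bar = gamma_hat.mean()
        tau2 = max(gamma_hat.var(ddof=1), 1e-12)
        d_bar = delta_hat.mean()
        d_var = max(delta_hat.var(ddof=1), 1e-12)
        # inverse-gamma(lambda, theta) moment match on the scale effects
        lam = (2 * d_var + d_bar**2) / d_var
        theta = (d_bar * d_var + d_bar**3) / d_var
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(self.max_iter):
            g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (
                nb * tau2 + delta_star
            )
            ss = ((Zb - g_new) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * ss) / (nb / 2 + lam - 1)
            change = max(
                np.abs(g_new - gamma_star).max(initial=0.0),
                np.abs(d_new - delta_star).max(initial=0.0),
            )
            gamma_star, delta_star = g_new, d_new
            if change < self.tol:
                break
        return gamma_star, np.maximum(delta_star, 1e-12)


def merge_datasets(esets: list[ExpressionSet], adjust: bool = True, method: str = "eb") -> ExpressionSet:
    """Merge gene-level datasets by matching gene symbols, with optional
    empirical-Bayes batch adjustment across datasets.

    Genes are restricted to the symbols common to every dataset; columns are
    concatenated in input order.  With ``adjust`` on, dataset id is treated
    as the batch label and per-gene additive/multiplicative batch effects
    are removed with :class:`EmpiricalBayesBatchCorrector`; cohort labels
    and other metadata are untouched.
    """
    if len(esets) < 2:
        raise ValueError("need at least two datasets to merge")
    for eset in esets:
        if eset.row_level != "gene":
            raise ValueError("merge_datasets expects gene-level ExpressionSets")
        if any(not s.dataset_id for s in eset.samples):
            raise ValueError("every sample needs a dataset_id")
    shared = esets[0].row_ids
    for eset in esets[1:]:
        shared = shared.intersection(eset.row_ids)
    if len(shared) == 0:
        raise ValueError("no genes shared across datasets")
    shared = sorted(shared)
    values = pd.concat([e.values.loc[shared] for e in esets], axis=1)
    if values.columns.duplicated().any():
        raise ValueError("sample ids collide across datasets")
    samples = [s for e in esets for s in e.samples]
    merged = ExpressionSet(values, samples, row_level="gene")
    merged.log_step(
        "merge_datasets",
        n_datasets=len(esets),
        n_shared_genes=len(shared),
        adjust=adjust,
    )
    if not adjust:
        return merged
    batch = merged.dataset_ids
    corrector = EmpiricalBayesBatchCorrector(method=method)
    adjusted = corrector.fit_transform(merged.values.to_numpy().T, batch).T
    merged.values = pd.DataFrame(adjusted, index=merged.values.index, columns=merged.values.columns)
    merged.log_step("batch_adjust", method=method, batches=list(corrector.batches_))
    return merged
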