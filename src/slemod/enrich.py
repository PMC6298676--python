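"""Single-sample gene-set enrichment and functional-category tests.

Per-sample gene-set scores follow the non-parametric KS-like random-walk
construction: expression values are first reduced, per gene, to a rank-based
z statistic (empirical CDF rank mapped through the standard normal
quantile function — invariant to any monotone per-gene transform of the
data), then for each sample the genes are ordered by decreasing |z| and a
weighted Kolmogorov-Smirnov walk over the ordered list yields the set
score.  Category enrichment of DE gene lists against a background uses a
2x2 chi-squared test (1 df, no continuity correction) with an exact-test
fallback when expected counts drop below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ExpressionSet, GeneSetCollection

__all__ = [
    "EnrichmentMatrix",
    "CategoryEnrichment",
    "GeneSetScorer",
    "gene_level_stats",
    "score_gene_sets",
    "category_enrichment",
]


@dataclass
class EnrichmentMatrix:
    """Samples x gene-sets single-sample enrichment scores.

    Scores lie in [-1, 1]; sets with no overlap against the expression
    matrix yield missing columns.  ``overlap`` records the per-set overlap
    size actually scored.
    """

    scores: pd.DataFrame
    tau: float = 1.0
    mode: str = "diff"
    overlap: dict[str, int] = field(default_factory=dict)


def gene_level_stats(eset_or_values) -> pd.DataFrame:
    """Rank-based per-gene z statistics (genes x samples).

    Each gene's values are converted to midranks across samples, scaled to
    rank/(n+1), and mapped through the standard normal quantile function.
    Constant genes get statistic 0 in every sample.
    """
    if isinstance(eset_or_values, ExpressionSet):
        values = eset_or_values.values
    elif isinstance(eset_or_values, pd.DataFrame):
        values = eset_or_values.astype(float)
    else:
        values = pd.DataFrame(np.asarray(eset_or_values, dtype=float))
    n = values.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for rank statistics")
    ranks = np.apply_along_axis(
        lambda row: stats.rankdata(row, method="average"), 1, values.to_numpy()
    )
    z = stats.norm.ppf(ranks / (n + 1))
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def _walk_score(z: np.ndarray, in_set: np.ndarray, tau: float, mode: str) -> float:
    """KS-like random-walk score for one sample.

    Genes are ordered by decreasing statistic (stable ties); the walk steps
    up by |z|^tau (normalized over in-set genes) at in-set positions and
    down by 1/(N - m) otherwise, so coordinately *high* set genes push the
    walk up early and coordinately *low* set genes pull it down late.
    ``diff`` returns ES+ - ES-; ``maxabs`` the deviation of largest
    magnitude with its sign.  The signed ordering makes the null
    distribution of diff scores symmetric around zero (the weight profile
    |z|^tau is symmetric across the two ends of the ranked list) and
    negates a sample's score when its statistics are sign-flipped.
    """
    order = np.argsort(-z, kind="stable")
    hit = in_set[order]
    w = np.abs(z[order]) ** tau
    w_in = np.where(hit, w, 0.0)
    total = w_in.sum()
    m = int(hit.sum())
    n_out = z.size - m
    if total > 0:
        up = w_in / total
    else:  # all in-set statistics are zero: uniform up-steps
        up = np.where(hit, 1.0 / m, 0.0)
    steps = up - np.where(hit, 0.0, 1.0 / n_out)
    walk = np.cumsum(steps)
    es_plus = max(walk.max(initial=0.0), 0.0)
    es_minus = max(-walk.min(initial=0.0), 0.0)
    if mode == "diff":
        return float(es_plus - es_minus)
    return float(es_plus if es_plus >= es_minus else -es_minus)


def score_gene_sets(
    stats_matrix: pd.DataFrame,
    collection: GeneSetCollection,
    tau: float = 1.0,
    mode: str = "diff",
) -> EnrichmentMatrix:
    """Score every gene set in every sample from a genes x samples statistic
    matrix (see :func:`gene_level_stats`).

    Sets are intersected with the matrix rows first; a set covering *all*
    genes is an error (the down-step is undefined) and a set with empty
    overlap yields missing scores with a warning.
    """
    if mode not in ("diff", "maxabs"):
        raise ValueError("mode must be 'diff' or 'maxabs'")
    Z = stats_matrix.to_numpy()
    genes = stats_matrix.index
    gene_pos = {gene: i for i, gene in enumerate(genes)}
    n_genes, n_samples = Z.shape
    scores = np.full((n_samples, len(collection)), np.nan)
    overlap: dict[str, int] = {}
    for j, name in enumerate(collection.names):
        idx = [gene_pos[g] for g in collection[name] if g in gene_pos]
        overlap[name] = len(idx)
        if len(idx) == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix", stacklevel=2)
            continue
        if len(idx) >= n_genes:
            raise ValueError(f"gene set {name!r} covers every gene in the matrix")
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[idx] = True
        for s in range(n_samples):
            scores[s, j] = _walk_score(Z[:, s], in_set, tau, mode)
    frame = pd.DataFrame(scores, index=stats_matrix.columns, columns=collection.names)
    return EnrichmentMatrix(scores=frame, tau=tau, mode=mode, overlap=overlap)


class GeneSetScorer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: expression (samples x genes) -> set scores.

    Parameters
    ----------
    gene_sets : GeneSetCollection
    tau : weight exponent on |z| for the up-steps (default 1)
    mode : {"diff", "maxabs"} score mode

    ``transform`` expects a DataFrame with gene-symbol columns (or an array
    plus ``genes`` given at construction).
    """

    def __init__(self, gene_sets: GeneSetCollection, tau: float = 1.0, mode: str = "diff", genes=None):
        self.gene_sets = gene_sets
        self.tau = tau
        self.mode = mode
        self.genes = genes

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            values = X.T  # genes x samples
        else:
            X = np.asarray(X, dtype=float)
            genes = self.genes if self.genes is not None else [f"g{i}" for i in range(X.shape[1])]
            values = pd.DataFrame(X.T, index=list(genes))
        z = gene_level_stats(values)
        return score_gene_sets(z, self.gene_sets, tau=self.tau, mode=self.mode).scores

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


@dataclass
class CategoryEnrichment:
    """Per-category 2x2 enrichment results of a DE list vs background."""

    table: pd.DataFrame
    alpha: float = 0.05


def category_enrichment(
    de_genes, background, categories: GeneSetCollection, alpha: float = 0.05
) -> CategoryEnrichment:
    """Chi-squared enrichment of functional categories in a DE gene list.

    For each category, the 2x2 table (DE / not-DE x in / out of category)
    over the background is tested with a 1-df chi-squared statistic (no
    continuity correction); when any expected cell is below 1 the exact
    (Fisher) test replaces it, recorded in the ``method`` column.
    Categories with p < ``alpha`` are flagged significant.
    """
    de = set(de_genes)
    bg = list(dict.fromkeys(background))
    if not de.issubset(bg):
        raise ValueError("de_genes must be a subset of the background")
    n_bg = len(bg)
    n_de = len(de)
    rows = []
    for name in categories.names:
        cat = set(categories[name]) & set(bg)
        a = len(de & cat)  # DE, in category
        b = n_de - a  # DE, out
        c = len(cat) - a  # not DE, in
        d = n_bg - n_de - c
        table = np.array([[a, b], [c, d]], dtype=float)
        row_sums = table.sum(axis=1, keepdims=True)
        col_sums = table.sum(axis=0, keepdims=True)
        if (row_sums == 0).any() or (col_sums == 0).any():
            chi2, p, method = 0.0, 1.0, "degenerate"
        else:
            expected = row_sums @ col_sums / table.sum()
            if expected.min() < 1.0:
                _, p = stats.fisher_exact(table.astype(int))
                chi2, method = np.nan, "fisher_exact"
            else:
                chi2 = float(((table - expected) ** 2 / expected).sum())
                p = float(stats.chi2.sf(chi2, df=1))
                method = "chi2"
        rows.append(
            {
                "category": name,
                "n_de_in": a,
                "n_de_out": b,
                "n_bg_in": a + c,
                "n_bg_out": b + d,
                "chi2": chi2,
                "p": p,
                "method": method,
                "significant": p < alpha,
            }
        )
    return CategoryEnrichment(table=pd.DataFrame(rows).set_index("category"), alpha=alpha)
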