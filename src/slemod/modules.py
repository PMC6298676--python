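"""Weighted co-expression module discovery.

Builds an unsigned weighted gene network (adjacency ``|cor|^beta`` with the
soft-threshold power ``beta`` chosen for approximate scale-free topology),
summarizes shared neighborhoods with the topological overlap matrix (TOM),
clusters genes on TOM dissimilarity with average-linkage hierarchical
clustering, refines assignments with a partitioning-around-medoids-style
reattachment step, merges modules whose eigengenes are highly correlated,
and characterizes modules by eigengene (first principal component), kME
(gene-eigengene correlation), mean-kME quality and module-trait
correlations (Pearson for continuous traits, point-biserial for
dichotomous ones).

Tree cutting here is a deterministic simplification of the dynamic hybrid
algorithm: candidate cut heights are scanned over the dendrogram's merge
heights (below ``detect_cut``) and the cut maximizing the number of
admissible clusters — at least ``min_size`` genes and mean within-cluster
TOM at least 1.5x the matrix-wide mean — is selected, with ties going to
the lower (finer) cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .data import ExpressionSet, SampleMeta

__all__ = [
    "TOMatrix",
    "ModuleSet",
    "CoexpressionModules",
    "pick_soft_threshold",
    "compute_tom",
    "detect_modules",
    "module_eigengene",
    "compute_kme_and_reassign",
    "correlate_module_traits",
    "grand_mean_kme",
]

UNASSIGNED = "unassigned"

# Conventional semi-random color labels, assigned in decreasing module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen",
]

# Admissibility of a candidate cluster: its mean within-cluster |cor| must
# exceed this multiple of the null level E|cor| ~ sqrt(2/pi)/sqrt(n-1) for
# independent Gaussian profiles (selection effects in the clustering inflate
# noise clusters to roughly 1.5-2x the null level; real modules sit higher).
_COEXPRESSION_FACTOR = 2.5
_MAX_CANDIDATE_CUTS = 80


@dataclass
class TOMatrix:
    """Topological overlap matrix over an ordered gene list."""

    genes: list[str]
    power: float
    tom: np.ndarray

    def __post_init__(self) -> None:
        t = self.tom
        if t.shape[0] != t.shape[1] or t.shape[0] != len(self.genes):
            raise ValueError("TOM shape must match gene list")
        if np.abs(t - t.T).max(initial=0.0) > 1e-12:
            raise ValueError("TOM must be symmetric")
        if t.min() < -1e-12 or t.max() > 1 + 1e-12:
            raise ValueError("TOM values must lie in [0, 1]")

    @property
    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.tom
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)


@dataclass
class ModuleSet:
    """Module assignment plus eigengene/kME summaries.

    assignment : gene -> color label (or "unassigned")
    eigengenes : samples x modules, each column unit-norm
    kme : genes x modules Pearson correlations with the eigengenes
    mean_kme : per-module mean kME over member genes (quality metric)
    low_quality : modules with mean kME below 0.3
    """

    assignment: pd.Series
    eigengenes: pd.DataFrame
    kme: pd.DataFrame
    mean_kme: pd.Series
    params: dict = field(default_factory=dict)
    low_quality: list[str] = field(default_factory=list)
    grand_mean_kme: pd.Series | None = None

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def members(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


def _correlation(X: np.ndarray) -> np.ndarray:
    """Row-row Pearson correlation (genes x genes); constant rows raise."""
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant gene rows present; remove before network analysis")
    return np.clip(np.corrcoef(X), -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins on the log10
    scale; the fit is the squared Pearson correlation between log10 mean
    connectivity and log10 frequency over the non-empty bins.
    """
    k = connectivity[connectivity > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def pick_soft_threshold(
    eset_or_matrix,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power for approximate scale-free topology.

    For each candidate power the unsigned adjacency ``|cor|^beta`` is formed
    and the scale-free fit R^2 of the connectivity distribution computed;
    the smallest power reaching ``r2_target`` is returned, or, if none
    reaches it, the power with the best fit (with a warning).  Also returns
    the per-power diagnostic table (power, r2, mean_k).
    """
    X = _as_gene_matrix(eset_or_matrix)
    if X.shape[1] < 8:
        raise ValueError("need at least 8 samples to assess scale-free fit")
    powers = sorted(float(p) for p in candidate_powers)
    if any(p <= 0 for p in powers):
        raise ValueError("candidate powers must be positive")
    abscor = np.abs(_correlation(X))
    np.fill_diagonal(abscor, 0.0)
    rows = []
    for p in powers:
        a = abscor**p
        k = a.sum(axis=1)
        rows.append({"power": p, "r2": scale_free_fit(k), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= r2_target]
    if len(ok):
        best = float(ok.iloc[0]["power"])
    else:
        best = float(table.loc[table["r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached scale-free R^2 {r2_target}; "
            f"using best fit (power={best})",
            stacklevel=2,
        )
    return best, table


def _as_gene_matrix(eset_or_matrix) -> np.ndarray:
    """Genes x samples float array from an ExpressionSet or array-like."""
    if isinstance(eset_or_matrix, ExpressionSet):
        return eset_or_matrix.values.to_numpy()
    return np.asarray(eset_or_matrix, dtype=float)


def _gene_ids(eset_or_matrix, n: int) -> list[str]:
    if isinstance(eset_or_matrix, ExpressionSet):
        return list(eset_or_matrix.row_ids)
    return [f"g{i}" for i in range(n)]


def compute_tom(eset_or_matrix, power: float) -> TOMatrix:
    """Unsigned topological overlap matrix at soft-threshold ``power``.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    a = |cor|^power (a_ii treated as 0), TOM_ii = 1.
    """
    X = _as_gene_matrix(eset_or_matrix)
    a = np.abs(_correlation(X)) ** power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum over u != i, j since diag(a) = 0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(genes=_gene_ids(eset_or_matrix, X.shape[0]), power=float(power), tom=tom)


def module_eigengene(eset_or_matrix, member_genes=None) -> tuple[pd.Series, float]:
    """Module eigengene: first principal component of the member genes.

    Member genes are standardized across samples; the eigengene is the
    unit-norm first right singular vector, sign-oriented so its mean
    correlation with the member genes is non-negative.  Returns the
    eigengene and the fraction of variance it explains.  Constant genes are
    dropped with a warning; fewer than two usable genes raise.
    """
    if isinstance(eset_or_matrix, ExpressionSet):
        if member_genes is None:
            member_genes = list(eset_or_matrix.row_ids)
        X = eset_or_matrix.values.loc[list(member_genes)].to_numpy()
        sample_index = pd.Index(eset_or_matrix.sample_ids)
    else:
        X = np.asarray(eset_or_matrix, dtype=float)
        if member_genes is not None:
            X = X[list(member_genes)]
        sample_index = pd.RangeIndex(X.shape[1])
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("dropping constant genes from eigengene calculation", stacklevel=2)
        X = X[sd > 0]
        sd = sd[sd > 0]
    if X.shape[0] < 2:
        raise ValueError("eigengene needs at least two non-constant member genes")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    if np.mean([np.corrcoef(me, row)[0, 1] for row in Z]) < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(me, index=sample_index, name="ME"), var_explained


def _eigengene_matrix(values: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    mes = {}
    for mod in [m for m in assignment.unique() if m != UNASSIGNED]:
        members = assignment.index[assignment == mod]
        me, _ = module_eigengene(values.loc[members].to_numpy())
        mes[mod] = me.to_numpy()
    return pd.DataFrame(mes, index=values.columns)


def _candidate_cut(
    tom: TOMatrix,
    abscor: np.ndarray,
    admission_floor: float,
    Z: np.ndarray,
    detect_cut: float,
    min_size: int,
) -> np.ndarray:
    """Cluster labels (ints, -1 = unassigned) from the best admissible cut.

    Candidate cut heights are the dendrogram merge heights below
    ``detect_cut`` (subsampled to a fixed grid for large trees).  A cluster
    is admissible when it has at least ``min_size`` genes and its mean
    within-cluster |cor| exceeds the noise-calibrated co-expression floor.
    Each cut is scored by the summed TOM quality of its admissible clusters,
    sum of size * (mean within-cluster TOM - matrix mean off-diagonal TOM),
    which favors pure tight clusters over mixtures diluted with background
    genes; ties keep the lower (finer) cut.
    """
    n = len(tom.genes)
    heights = np.unique(Z[:, 2])
    heights = heights[heights < detect_cut]
    if heights.size == 0:
        return np.full(n, -1)
    if heights.size > _MAX_CANDIDATE_CUTS:
        picks = np.linspace(0, heights.size - 1, _MAX_CANDIDATE_CUTS).round().astype(int)
        heights = heights[np.unique(picks)]
    cuts = cut_tree(Z, height=heights)  # genes x n_heights
    off_mean = tom.tom[~np.eye(n, dtype=bool)].mean()

    best_labels, best_score = np.full(n, -1), 0.0
    for j in range(heights.size):
        labels = cuts[:, j]
        out = np.full(n, -1)
        score, next_label = 0.0, 0
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if idx.size < min_size:
                continue
            cor_block = abscor[np.ix_(idx, idx)]
            within_cor = (cor_block.sum() - idx.size) / (idx.size * (idx.size - 1))
            if within_cor < admission_floor:
                continue
            block = tom.tom[np.ix_(idx, idx)]
            within = (block.sum() - idx.size) / (idx.size * (idx.size - 1))
            out[idx] = next_label
            next_label += 1
            score += idx.size * (within - off_mean)
        if score > best_score + 1e-15:  # ties keep the lower (finer) cut
            best_labels, best_score = out, score
    return best_labels


def _pam_reattach(tom: TOMatrix, labels: np.ndarray) -> np.ndarray:
    """PAM-style refinement on TOM distance.

    Assigned genes move to the cluster with the smallest average
    dissimilarity if strictly closer than to their own; unassigned genes
    attach to their nearest cluster when closer than the midpoint between
    that cluster's internal mean dissimilarity and the matrix-wide mean.
    """
    D = tom.dissimilarity
    n = D.shape[0]
    clusters = np.unique(labels[labels >= 0])
    if clusters.size == 0:
        return labels
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    sizes = np.array([members[c].size for c in clusters], dtype=float)
    sums = np.stack([D[:, members[c]].sum(axis=1) for c in clusters], axis=1)
    avg = sums / sizes  # gene x cluster mean dissimilarity
    # own-cluster averages must exclude the gene itself
    for ci, c in enumerate(clusters):
        idx = members[c]
        if idx.size > 1:
            avg[idx, ci] = (sums[idx, ci]) / (sizes[ci] - 1)
    d_within = {
        c: (D[np.ix_(members[c], members[c])].sum() / (members[c].size * (members[c].size - 1)))
        for c in clusters
    }
    d_global = D[~np.eye(n, dtype=bool)].mean()
    out = labels.copy()
    nearest = np.argmin(avg, axis=1)
    for g in range(n):
        ci = nearest[g]
        c = clusters[ci]
        if labels[g] >= 0:
            own = np.flatnonzero(clusters == labels[g])[0]
            if avg[g, ci] < avg[g, own]:
                out[g] = c
        else:
            if avg[g, ci] < 0.5 * (d_within[c] + d_global):
                out[g] = c
    return out


def _merge_by_eigengene(
    values: pd.DataFrame, assignment: pd.Series, merge_cut: float
) -> pd.Series:
    """Iteratively merge the closest module pair while ME dissimilarity < cut."""
    assignment = assignment.copy()
    while True:
        modules = sorted(m for m in assignment.unique() if m != UNASSIGNED)
        if len(modules) < 2:
            return assignment
        me = _eigengene_matrix(values, assignment)[modules]
        cor = np.corrcoef(me.to_numpy().T)
        best_pair, best_diss = None, merge_cut
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                diss = 1.0 - cor[i, j]
                if diss < best_diss:
                    best_pair, best_diss = (modules[i], modules[j]), diss
        if best_pair is None:
            return assignment
        keep, absorb = best_pair
        assignment[assignment == absorb] = keep


def detect_modules(
    tom: TOMatrix,
    eset_or_matrix,
    detect_cut: float = 1.0,
    merge_cut: float = 0.2,
    min_size: int = 30,
    pam: bool = True,
) -> ModuleSet:
    """Detect co-expression modules from a TOM.

    Average-linkage hierarchical clustering on 1 - TOM; the cut height is
    scanned below ``detect_cut`` for the maximal number of admissible
    clusters (see module docstring); clusters below ``min_size`` dissolve
    to unassigned; with ``pam`` on, genes are reattached to their nearest
    cluster by average TOM distance; modules whose eigengenes have
    dissimilarity 1 - cor below ``merge_cut`` are merged iteratively.
    Final labels are colors in decreasing module-size order.
    """
    if isinstance(eset_or_matrix, ExpressionSet):
        values = eset_or_matrix.values
    else:
        X = np.asarray(eset_or_matrix, dtype=float)
        values = pd.DataFrame(X, index=tom.genes)
    if list(values.index) != list(tom.genes):
        raise ValueError("TOM gene order must match the expression matrix")
    n = len(tom.genes)
    params = {
        "power": tom.power,
        "detect_cut": detect_cut,
        "merge_cut": merge_cut,
        "min_size": min_size,
        "pam": pam,
    }
    if n < min_size:
        assignment = pd.Series(UNASSIGNED, index=values.index, name="module")
        return ModuleSet(
            assignment=assignment,
            eigengenes=pd.DataFrame(index=values.columns),
            kme=pd.DataFrame(index=values.index),
            mean_kme=pd.Series(dtype=float),
            params=params,
        )
    Z = linkage(squareform(tom.dissimilarity, checks=False), method="average")
    abscor = np.abs(_correlation(values.to_numpy()))
    n_samples = values.shape[1]
    # null level of |cor| for independent Gaussian profiles: sqrt(2/pi)/sqrt(n-1)
    admission_floor = _COEXPRESSION_FACTOR * np.sqrt(2 / np.pi) / np.sqrt(n_samples - 1)
    labels = _candidate_cut(tom, abscor, admission_floor, Z, detect_cut, min_size)
    if pam and (labels >= 0).any():
        labels = _pam_reattach(tom, labels)
    assignment = pd.Series(
        [f"m{l}" if l >= 0 else UNASSIGNED for l in labels],
        index=values.index,
        name="module",
    )
    if (assignment != UNASSIGNED).any():
        assignment = _merge_by_eigengene(values, assignment, merge_cut)
    # size-ordered color labels (ties by provisional label for determinism)
    sizes = assignment[assignment != UNASSIGNED].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    rename = {
        m: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, m in enumerate(order)
    }
    assignment = assignment.map(lambda m: rename.get(m, UNASSIGNED))
    eigengenes = _eigengene_matrix(values, assignment)
    eigengenes = eigengenes[[rename[m] for m in order]] if order else eigengenes
    module_set = ModuleSet(
        assignment=assignment,
        eigengenes=eigengenes,
        kme=pd.DataFrame(index=values.index),
        mean_kme=pd.Series(dtype=float),
        params=params,
    )
    return compute_kme_and_reassign(values, module_set, reassign=False)


def compute_kme_and_reassign(
    eset_or_values,
    module_set: ModuleSet,
    reassign: bool = True,
    kme_attach: float = 0.5,
) -> ModuleSet:
    """Compute kME (gene-eigengene correlations), optionally reassigning
    each gene to its highest-kME module, and recompute module quality.

    Final module membership follows the greatest within-module correlation
    with the module eigengene: assigned genes move to their argmax-kME
    module (ties keep the current module), and unassigned genes whose best
    kME reaches ``kme_attach`` are recruited into that module
    (``kme_attach=None`` disables recruitment).  Eigengenes and kME are
    recomputed once afterwards.  Modules with mean kME below 0.3 are
    flagged low-quality.
    """
    values = (
        eset_or_values.values
        if isinstance(eset_or_values, ExpressionSet)
        else pd.DataFrame(np.asarray(eset_or_values, dtype=float), index=module_set.assignment.index)
    )
    assignment = module_set.assignment.copy()
    modules = [m for m in module_set.eigengenes.columns]
    if not modules:
        return module_set

    def kme_matrix(assign: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
        me = _eigengene_matrix(values, assign)
        mods = list(me.columns)
        X = values.to_numpy()
        Zg = (X - X.mean(axis=1, keepdims=True))
        sd = X.std(axis=1)
        sd[sd == 0] = np.inf
        Zg = Zg / sd[:, None]
        M = me.to_numpy()
        Zm = (M - M.mean(axis=0)) / M.std(axis=0)
        kme = (Zg @ Zm) / X.shape[1]
        return pd.DataFrame(np.clip(kme, -1, 1), index=values.index, columns=mods), me

    kme, me = kme_matrix(assignment)
    if reassign:
        # iterate to a fixed point: eigengenes sharpen as membership improves
        for _ in range(10):
            assigned = assignment != UNASSIGNED
            best = kme.loc[assigned].idxmax(axis=1)
            current = assignment[assigned]
            best_val = kme.loc[assigned].max(axis=1)
            cur_val = pd.Series(
                [kme.at[g, m] for g, m in current.items()], index=current.index
            )
            move = best_val > cur_val + 1e-12  # ties keep current module
            proposal = assignment.copy()
            proposal.loc[move.index[move]] = best[move]
            if kme_attach is not None:
                free = ~assigned
                best_free = kme.loc[free].max(axis=1)
                recruit = best_free.index[best_free >= kme_attach]
                proposal.loc[recruit] = kme.loc[recruit].idxmax(axis=1)
            if proposal.equals(assignment):
                break
            assignment = proposal
            kme, me = kme_matrix(assignment)
    mods = list(me.columns)
    mean_kme = pd.Series(
        {
            m: float(kme.loc[assignment == m, m].mean())
            for m in mods
        }
    )
    low_quality = [m for m in mods if mean_kme[m] < 0.3]
    return ModuleSet(
        assignment=assignment,
        eigengenes=me,
        kme=kme,
        mean_kme=mean_kme,
        params=dict(module_set.params),
        low_quality=low_quality,
        grand_mean_kme=module_set.grand_mean_kme,
    )


def grand_mean_kme(module_sets: list[ModuleSet]) -> pd.Series:
    """Across-dataset module quality: mean of the per-dataset mean kMEs."""
    frames = [ms.mean_kme for ms in module_sets]
    return pd.concat(frames, axis=1).mean(axis=1)


def correlate_module_traits(
    module_set: ModuleSet, samples: list[SampleMeta], traits: pd.DataFrame
) -> pd.DataFrame:
    """Correlate module eigengenes with sample traits.

    ``traits`` is a samples x traits DataFrame aligned with the eigengene
    rows.  Traits with exactly two distinct values are treated as
    dichotomous (point-biserial correlation, computed as Pearson on the 0/1
    coding); all others as continuous (Pearson).  Two-sided p-values come
    from t = r sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    me = module_set.eigengenes
    if len(traits) != len(me):
        raise ValueError("traits must align with eigengene samples")
    rows = []
    for trait in traits.columns:
        t_raw = traits[trait].to_numpy()
        levels = np.unique(t_raw)
        if levels.size < 2:
            raise ValueError(f"trait {trait!r} has zero variance")
        if levels.size == 2:
            kind = "dichotomous"
            t_vals = (t_raw == levels[1]).astype(float)
        else:
            kind = "continuous"
            t_vals = t_raw.astype(float)
        n = t_vals.size
        for mod in me.columns:
            r = float(np.corrcoef(me[mod].to_numpy(), t_vals)[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
            rows.append(
                {"module": mod, "trait": trait, "r": r, "p": p, "trait_kind": kind, "n": n}
            )
    return pd.DataFrame(rows)


class CoexpressionModules(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper for the full module-discovery pipeline.

    ``fit(X)`` with X of shape (n_samples, n_genes): picks the
    soft-threshold power (unless given), computes the TOM, detects and
    merges modules, and performs a kME reassignment pass.

    Fitted attributes: ``power_``, ``tom_``, ``labels_`` (per-gene module
    label array), ``module_set_`` (full :class:`ModuleSet`).
    """

    def __init__(
        self,
        power=None,
        detect_cut: float = 1.0,
        merge_cut: float = 0.2,
        min_size: int = 30,
        pam: bool = True,
        r2_target: float = 0.8,
    ):
        self.power = power
        self.detect_cut = detect_cut
        self.merge_cut = merge_cut
        self.min_size = min_size
        self.pam = pam
        self.r2_target = r2_target

    def fit(self, X, y=None):
        G = np.asarray(X, dtype=float).T  # genes x samples
        if self.power is None:
            self.power_, self.sft_table_ = pick_soft_threshold(G, r2_target=self.r2_target)
        else:
            self.power_ = float(self.power)
        self.tom_ = compute_tom(G, self.power_)
        module_set = detect_modules(
            self.tom_,
            G,
            detect_cut=self.detect_cut,
            merge_cut=self.merge_cut,
            min_size=self.min_size,
            pam=self.pam,
        )
        self.module_set_ = compute_kme_and_reassign(
            pd.DataFrame(G, index=module_set.assignment.index), module_set
        )
        self.labels_ = self.module_set_.assignment.to_numpy()
        return self
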