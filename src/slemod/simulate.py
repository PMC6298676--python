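"""Synthetic expression data with planted structure.

Generates log2 expression matrices that emulate the study design the rest
of the package analyzes: three cohorts (healthy controls, inactive SLE,
active SLE) with integer SLEDAI scores; planted co-expression modules whose
latent factors correlate with SLEDAI to a configured degree; M1/M2
macrophage-polarization signature genes with cohort-dependent fold changes
(M1 up in both SLE cohorts, more in active; M2 up in both, more in
inactive); and multiple datasets with per-gene additive batch offsets.

The generative model for gene g in sample s is

    x_gs = mu_g + lambda_g * f_{m(g),s} + beta_{g,cohort(s)} + eps_gs

with eps ~ Normal(0, noise_sd^2).  Module factors are tied to SLEDAI via a
Gaussian copula on the SLEDAI ranks, calibrated so the realized Pearson
correlation with SLEDAI matches the configured target in expectation.
Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    HC,
    SLE_ACTIVE,
    SLE_INACTIVE,
    ExpressionSet,
    GeneSetCollection,
    SampleMeta,
    write_expression_tsv,
    write_gmt,
)

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_collection",
    "write_fixtures",
    "activity_scenario",
]


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    size : number of member genes (>= 3)
    factor_loading : loading of member genes on the module factor, in (0, 1]
    trait_corr : target Pearson correlation of the factor with SLEDAI, |r| < 1
    """

    size: int = 100
    factor_loading: float = 0.8
    trait_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("module size must be >= 3")
        if not 0 < self.factor_loading <= 1:
            raise ValueError("factor_loading must be in (0, 1]")
        if abs(self.trait_corr) >= 1:
            raise ValueError("|trait_corr| must be < 1")


def _default_modules() -> list[ModuleSpec]:
    # Trait correlations are kept weakly collinear on purpose: all module
    # factors correlate with SLEDAI through the same Gaussian-copula image
    # of the trait, so pairs of strong same-magnitude targets (e.g. +0.8 and
    # -0.8) would force |cor(f_i, f_j)| ~ 0.6-0.7 between "distinct"
    # modules, making them a single co-expression unit in an unsigned
    # network rather than five planted modules.
    return [
        ModuleSpec(size=100, factor_loading=0.8, trait_corr=0.8),
        ModuleSpec(size=100, factor_loading=0.8, trait_corr=-0.5),
        ModuleSpec(size=100, factor_loading=0.8, trait_corr=0.35),
        ModuleSpec(size=100, factor_loading=0.8, trait_corr=-0.2),
        ModuleSpec(size=100, factor_loading=0.8, trait_corr=0.0),
    ]


def _default_lfc() -> dict[tuple[str, str], float]:
    # M1 up in both SLE cohorts, larger in active; M2 up in both, larger in
    # inactive (and near-null in active, where observed M2 direction is mixed).
    return {
        ("M1", SLE_ACTIVE): 2.0,
        ("M1", SLE_INACTIVE): 1.0,
        ("M2", SLE_ACTIVE): 0.3,
        ("M2", SLE_INACTIVE): 1.5,
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults emulate a small purified-cell microarray study: 40 samples
    (14 HC / 13 inactive / 13 active), 2000 genes of which five 100-gene
    modules carry latent-factor structure, 30 M1 and 30 M2 signature genes
    with the cohort fold-change pattern above, residual noise 1.0 on the
    log2 scale, and (for multi-dataset collections) three datasets with
    per-gene batch offsets of SD 1.0.
    """

    n_hc: int = 14
    n_inactive: int = 13
    n_active: int = 13
    n_genes: int = 2000
    modules: list[ModuleSpec] = field(default_factory=_default_modules)
    m1_genes: int = 30
    m2_genes: int = 30
    lfc: dict[tuple[str, str], float] = field(default_factory=_default_lfc)
    noise_sd: float = 1.0
    n_datasets: int = 3
    batch_shift_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hc", "n_inactive", "n_active", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        total_module = sum(m.size for m in self.modules)
        if total_module + self.m1_genes + self.m2_genes > self.n_genes:
            raise ValueError("module and signature genes exceed n_genes")

    @property
    def n_samples(self) -> int:
        return self.n_hc + self.n_inactive + self.n_active


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    module_of_gene: dict[str, str | None]
    signature_of_gene: dict[str, str | None]
    latent_factors: pd.DataFrame  # samples x modules
    labels: list[str]
    sledai: list[float]
    seed: int

    def module_gene_sets(self) -> GeneSetCollection:
        sets: dict[str, list[str]] = {}
        for gene, mod in self.module_of_gene.items():
            if mod is not None:
                sets.setdefault(mod, []).append(gene)
        return GeneSetCollection(sets, {m: "planted module" for m in sets})

    def signature_gene_sets(self) -> GeneSetCollection:
        sets: dict[str, list[str]] = {}
        for gene, sig in self.signature_of_gene.items():
            if sig is not None:
                sets.setdefault(sig, []).append(gene)
        return GeneSetCollection(sets, {s: "planted signature" for s in sets})


def _draw_sledai(rng: np.random.Generator, config: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    cohorts = (
        [HC] * config.n_hc
        + [SLE_INACTIVE] * config.n_inactive
        + [SLE_ACTIVE] * config.n_active
    )
    sledai = np.concatenate(
        [
            np.zeros(config.n_hc),
            rng.integers(0, 6, size=config.n_inactive),  # inactive: 0..5
            rng.integers(6, 21, size=config.n_active),  # active: 6..20
        ]
    ).astype(float)
    return cohorts, sledai


def _trait_linked_factor(
    rng: np.random.Generator, sledai: np.ndarray, rho: float
) -> np.ndarray:
    """Factor with Pearson correlation ~= rho with SLEDAI (Gaussian copula).

    Normal scores of the SLEDAI midranks give the monotone Gaussian image of
    the trait; the effective copula correlation is inflated by the (slightly
    sub-unit) correlation between trait and scores so the realized Pearson
    correlation with SLEDAI itself hits the target in expectation.
    """
    n = sledai.size
    noise = rng.standard_normal(n)
    if rho == 0:
        # exact null link: remove the factor's sample projection on the trait
        t = sledai - sledai.mean()
        if t @ t > 0:
            noise = noise - (noise @ t) / (t @ t) * t
        return (noise - noise.mean()) / noise.std()
    z = stats.norm.ppf(stats.rankdata(sledai, method="average") / (n + 1))
    z = (z - z.mean()) / z.std()
    c = np.corrcoef(z, sledai)[0, 1]
    rho_eff = np.clip(rho / max(c, 1e-6), -0.999, 0.999)
    # orthogonalize the residual against both the normal scores and the raw
    # trait so the factor's sample correlation with SLEDAI is exactly rho
    basis = np.column_stack([z, sledai - sledai.mean()])
    q, _ = np.linalg.qr(basis)
    resid = noise - q @ (q.T @ noise)
    resid = (resid - resid.mean()) / resid.std()
    return rho_eff * z + np.sqrt(1 - rho_eff**2) * resid


def generate_dataset(
    config: SyntheticConfig,
    seed: int | None = None,
    dataset_id: str = "D1",
) -> tuple[ExpressionSet, SyntheticTruth]:
    """Generate one dataset and its planted truth.

    Gene layout: module genes first (module_1, module_2, ...), then M1 and
    M2 signature genes, then unstructured background genes.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n, g = config.n_samples, config.n_genes
    cohorts, sledai = _draw_sledai(rng, config)
    genes = [f"G{i:05d}" for i in range(1, g + 1)]
    sample_ids = [f"{dataset_id}_s{i:03d}" for i in range(1, n + 1)]

    module_of: dict[str, str | None] = {gene: None for gene in genes}
    signature_of: dict[str, str | None] = {gene: None for gene in genes}
    loading = np.zeros(g)
    factor_idx = np.full(g, -1)
    pos = 0
    factors = {}
    for k, spec in enumerate(config.modules):
        label = f"module_{k + 1}"
        factors[label] = _trait_linked_factor(rng, sledai, spec.trait_corr)
        for gene in genes[pos : pos + spec.size]:
            module_of[gene] = label
        loading[pos : pos + spec.size] = spec.factor_loading
        factor_idx[pos : pos + spec.size] = k
        pos += spec.size
    for gene in genes[pos : pos + config.m1_genes]:
        signature_of[gene] = "M1"
    pos += config.m1_genes
    for gene in genes[pos : pos + config.m2_genes]:
        signature_of[gene] = "M2"

    mu = rng.uniform(5.0, 10.0, size=g)
    factor_matrix = np.vstack([factors[f"module_{k + 1}"] for k in range(len(config.modules))]) if config.modules else np.zeros((0, n))

    X = np.tile(mu[:, None], (1, n))
    has_factor = factor_idx >= 0
    X[has_factor] += loading[has_factor, None] * factor_matrix[factor_idx[has_factor]]
    # cohort-dependent signature shifts (log2 fold change vs HC)
    for sig in ("M1", "M2"):
        sig_rows = np.array([signature_of[gene] == sig for gene in genes])
        for cohort in (SLE_INACTIVE, SLE_ACTIVE):
            shift = config.lfc.get((sig, cohort), 0.0)
            cols = np.array([c == cohort for c in cohorts])
            X[np.ix_(sig_rows, cols)] += shift
    X += rng.normal(0.0, config.noise_sd, size=(g, n))

    samples = [
        SampleMeta(sample_id=sid, dataset_id=dataset_id, cohort=c, sledai=sl)
        for sid, c, sl in zip(sample_ids, cohorts, sledai)
    ]
    values = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=sample_ids)
    eset = ExpressionSet(values, samples, row_level="gene")
    eset.log_step("generate_dataset", seed=int(seed), dataset_id=dataset_id)
    truth = SyntheticTruth(
        module_of_gene=module_of,
        signature_of_gene=signature_of,
        latent_factors=pd.DataFrame(
            factor_matrix.T, index=sample_ids, columns=list(factors)
        ),
        labels=list(cohorts),
        sledai=sledai.tolist(),
        seed=int(seed),
    )
    return eset, truth


def generate_collection(
    config: SyntheticConfig, seed: int | None = None
) -> list[tuple[ExpressionSet, SyntheticTruth]]:
    """Generate ``config.n_datasets`` datasets sharing gene symbols and
    planted structure, each with independent samples and a per-gene additive
    batch offset drawn from Normal(0, batch_shift_sd^2)."""
    if config.n_datasets < 2:
        raise ValueError("n_datasets must be >= 2 for a collection")
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(config.n_datasets + 1)
    offset_rng = np.random.default_rng(children[0])
    out = []
    for k in range(config.n_datasets):
        child_seed = int(children[k + 1].generate_state(1)[0] % (2**31))
        eset, truth = generate_dataset(config, seed=child_seed, dataset_id=f"D{k + 1}")
        if config.batch_shift_sd > 0:
            offsets = offset_rng.normal(0.0, config.batch_shift_sd, size=eset.n_rows)
            eset.values = eset.values.add(offsets, axis=0)
            eset.log_step("batch_offset", sd=config.batch_shift_sd)
        out.append((eset, truth))
    return out


def activity_scenario(
    trait_corr: float = 0.8,
    with_effects: bool = True,
    n_genes: int = 1000,
    module_size: int = 100,
    n_null_modules: int = 3,
) -> SyntheticConfig:
    """Study conditions for the disease-activity classification experiment.

    One activity-linked module (its factor correlated ``trait_corr`` with
    SLEDAI, its first half overlapping the M1 signature so the activity
    cohorts also differ in mean — mirroring an M1-dominated activity
    module), plus ``n_null_modules`` null modules, across three datasets
    with batch offsets.  ``with_effects=False`` removes the activity link
    (factor-trait correlation and cohort fold changes) while keeping the
    module structure, as a negative control.
    """
    modules = [
        ModuleSpec(size=module_size, factor_loading=0.8, trait_corr=trait_corr if with_effects else 0.0)
    ] + [ModuleSpec(size=module_size, factor_loading=0.8, trait_corr=0.0) for _ in range(n_null_modules)]
    lfc = _default_lfc() if with_effects else {k: 0.0 for k in _default_lfc()}
    return SyntheticConfig(
        n_genes=n_genes,
        modules=modules,
        m1_genes=module_size // 2,
        m2_genes=30,
        lfc=lfc,
        n_datasets=3,
        batch_shift_sd=1.0,
    )


def generate_activity_collection(
    config: SyntheticConfig, seed: int | None = None
) -> list[tuple[ExpressionSet, SyntheticTruth]]:
    """Like :func:`generate_collection`, but the M1/M2 cohort shifts are
    applied to the *first module's* genes (first half M1-style up-shift)
    instead of separate signature genes, so the first module is both
    co-expressed and activity-shifted, as in an M1-dominated activity
    module."""
    if not config.modules:
        raise ValueError("activity collection needs at least one module")
    collection = generate_collection(config, seed=seed)
    first = config.modules[0]
    half = first.size // 2
    shift_active = config.lfc.get(("M1", SLE_ACTIVE), 0.0)
    shift_inactive = config.lfc.get(("M1", SLE_INACTIVE), 0.0)
    for eset, truth in collection:
        genes = list(eset.row_ids[:half])
        cohorts = eset.cohorts
        for cohort, shift in ((SLE_ACTIVE, shift_active), (SLE_INACTIVE, shift_inactive)):
            cols = eset.values.columns[cohorts == cohort]
            eset.values.loc[genes, cols] += shift
        for gene in genes:
            truth.signature_of_gene[gene] = "M1"
        eset.log_step("activity_overlay", n_genes=half)
    return collection


def write_fixtures(
    outdir, config: SyntheticConfig | None = None, seed: int | None = None
) -> dict:
    """Write a self-contained fixture directory and return its manifest.

    Emits ``expr.tsv`` and ``meta.tsv`` (expression matrix + metadata),
    ``polarization.gmt`` (planted M1/M2 signatures), ``categories.gmt``
    (planted modules as functional categories), ``truth.json`` and
    ``manifest.json``.
    """
    if config is None:
        config = SyntheticConfig()
    if seed is None:
        seed = config.seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eset, truth = generate_dataset(config, seed=seed)
    write_expression_tsv(eset, outdir / "expr.tsv", outdir / "meta.tsv")
    write_gmt(truth.signature_gene_sets(), outdir / "polarization.gmt")
    write_gmt(truth.module_gene_sets(), outdir / "categories.gmt")
    truth_json = {
        "module_of_gene": truth.module_of_gene,
        "signature_of_gene": truth.signature_of_gene,
        "labels": truth.labels,
        "sledai": truth.sledai,
        "seed": truth.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json) + "\n", encoding="utf-8")
    manifest = {
        "files": ["expr.tsv", "meta.tsv", "polarization.gmt", "categories.gmt", "truth.json"],
        "seed": int(seed),
        "n_genes": config.n_genes,
        "n_samples": config.n_samples,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
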