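"""Core data containers and file I/O.

The central container is :class:`ExpressionSet`, a log2 expression matrix
(rows = probes or genes, columns = samples) together with per-sample
clinical metadata (:class:`SampleMeta`).  Gene sets are carried by
:class:`GeneSetCollection` (read from standard GMT files) and probe-to-gene
maps by :class:`ProbeAnnotation`.

Disease-activity cohorts follow the clinical convention for the SLE Disease
Activity Index (SLEDAI): patients with SLEDAI < 6 are classified as inactive
and patients with SLEDAI >= 6 as active; healthy controls carry no (or zero)
SLEDAI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HC = "HC"
SLE_INACTIVE = "SLE_inactive"
SLE_ACTIVE = "SLE_active"
COHORTS = (HC, SLE_INACTIVE, SLE_ACTIVE)

#: SLEDAI score at or above which SLE is classified as active.
SLEDAI_ACTIVE_CUTOFF = 6.0


def assign_cohort(sledai: float, is_sle: bool) -> str:
    """Assign a disease-activity cohort from a SLEDAI score.

    Parameters
    ----------
    sledai : float
        SLE Disease Activity Index score (non-negative).
    is_sle : bool
        Whether the subject is an SLE patient; healthy controls are ``HC``
        regardless of score.

    Returns
    -------
    str
        One of ``"HC"``, ``"SLE_inactive"`` (SLEDAI < 6) or
        ``"SLE_active"`` (SLEDAI >= 6).
    """
    sledai = float(sledai)
    if sledai < 0:
        raise ValueError(f"SLEDAI must be non-negative, got {sledai}")
    if not is_sle:
        return HC
    return SLE_ACTIVE if sledai >= SLEDAI_ACTIVE_CUTOFF else SLE_INACTIVE


@dataclass
class SampleMeta:
    """Clinical metadata for a single sample."""

    sample_id: str
    dataset_id: str
    cohort: str
    sledai: float = 0.0
    extra_traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        self.sledai = float(self.sledai)
        if self.sledai < 0:
            raise ValueError(f"SLEDAI must be non-negative, got {self.sledai}")
        if self.cohort == HC:
            if self.sledai != 0:
                raise ValueError("healthy-control samples must have SLEDAI absent or 0")
        else:
            expected = assign_cohort(self.sledai, is_sle=True)
            if expected != self.cohort:
                raise ValueError(
                    f"cohort {self.cohort!r} inconsistent with SLEDAI {self.sledai} "
                    f"(rule assigns {expected!r})"
                )


@dataclass
class ExpressionSet:
    """Log2 expression matrix with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Finite log2 intensities, rows indexed by probe or gene identifiers,
        columns by sample ids.
    samples : list of SampleMeta
        One entry per column, in column order.
    row_level : {"probe", "gene"}
        Identifier level of the rows.  At gene level, row ids (gene symbols)
        must be unique.
    provenance : list of dict
        Free-form processing log; preprocessing steps append records here
        (thresholds chosen, rows removed, seeds used).
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    row_level: str = "probe"
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.row_level not in ("probe", "gene"):
            raise ValueError("row_level must be 'probe' or 'gene'")
        self.values = self.values.astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must all be finite")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row identifiers: {dupes[:5]}")
        if len(self.samples) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.samples)} SampleMeta entries for {self.values.shape[1]} columns"
            )
        for meta, col in zip(self.samples, self.values.columns):
            if meta.sample_id != col:
                raise ValueError(
                    f"sample metadata order mismatch: {meta.sample_id!r} vs column {col!r}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def cohorts(self) -> np.ndarray:
        return np.array([s.cohort for s in self.samples])

    @property
    def sledai(self) -> np.ndarray:
        return np.array([s.sledai for s in self.samples], dtype=float)

    @property
    def dataset_ids(self) -> np.ndarray:
        return np.array([s.dataset_id for s in self.samples])

    def metadata_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample id."""
        rows = []
        for s in self.samples:
            row = {"dataset_id": s.dataset_id, "cohort": s.cohort, "sledai": s.sledai}
            row.update(s.extra_traits)
            rows.append(row)
        return pd.DataFrame(rows, index=pd.Index(self.sample_ids, name="sample_id"))

    def subset_rows(self, row_ids) -> "ExpressionSet":
        return ExpressionSet(
            self.values.loc[list(row_ids)],
            self.samples,
            row_level=self.row_level,
            provenance=list(self.provenance),
        )

    def subset_samples(self, sample_ids) -> "ExpressionSet":
        keep = list(sample_ids)
        by_id = {s.sample_id: s for s in self.samples}
        missing = [s for s in keep if s not in by_id]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return ExpressionSet(
            self.values[keep],
            [by_id[s] for s in keep],
            row_level=self.row_level,
            provenance=list(self.provenance),
        )

    def log_step(self, step: str, **details) -> None:
        self.provenance.append({"step": step, **details})


@dataclass
class ProbeAnnotation:
    """Probe-to-gene map merged from a primary and a custom annotation source.

    ``entries`` maps each annotated probe to ``(gene_symbol, source)`` with
    source ``"primary"`` or ``"custom"``; ``excluded`` holds probes whose two
    sources disagreed on the gene and that are therefore dropped outright.
    """

    entries: dict[str, tuple[str, str]]
    excluded: set[str] = field(default_factory=set)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.excluded & set(self.entries)
        if overlap:
            raise ValueError(f"probes both annotated and excluded: {sorted(overlap)[:5]}")
        for probe, entry in self.entries.items():
            if entry[1] not in ("primary", "custom"):
                raise ValueError(f"bad annotation source {entry[1]!r} for {probe!r}")

    def gene_of(self, probe: str) -> str:
        return self.entries[probe][0]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. M1/M2 polarization signatures, functional categories)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            # preserve order, drop duplicates
            self.sets[name] = list(dict.fromkeys(members))
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# -- file formats -----------------------------------------------------------


def read_expression_tsv(path, metadata_path, row_level: str = "gene") -> ExpressionSet:
    """Read an expression matrix TSV plus a sample-metadata TSV.

    The matrix is tab-separated with row 1 = sample ids and column 1 = row
    ids.  Metadata must contain columns ``sample_id``, ``dataset_id``,
    ``cohort`` and ``sledai``; every matrix column needs a metadata row.
    Additional numeric metadata columns become ``extra_traits``.  Pass
    ``row_level="probe"`` for probe-level matrices.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        raise ValueError(f"duplicate row identifiers in {path}")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "dataset_id": str})
    required = {"sample_id", "dataset_id", "cohort", "sledai"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    missing = [c for c in values.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    extra_cols = [c for c in meta.columns if c not in ("dataset_id", "cohort", "sledai")]
    samples = []
    for col in values.columns:
        row = meta.loc[col]
        extras = {c: float(row[c]) for c in extra_cols if pd.notna(row[c])}
        samples.append(
            SampleMeta(
                sample_id=str(col),
                dataset_id=str(row["dataset_id"]),
                cohort=str(row["cohort"]),
                sledai=0.0 if pd.isna(row["sledai"]) else float(row["sledai"]),
                extra_traits=extras,
            )
        )
    return ExpressionSet(values, samples, row_level=row_level)


def write_expression_tsv(eset: ExpressionSet, path, metadata_path) -> None:
    """Write an ExpressionSet to matrix + metadata TSVs (inverse of reading)."""
    eset.values.to_csv(path, sep="\t", float_format="%.17g")
    eset.metadata_frame().to_csv(metadata_path, sep="\t")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a standard GMT file (name, description, members)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_annotation_tsv(path) -> dict[str, str]:
    """Read a two-column probe_id/gene_symbol TSV into a probe->gene map."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: annotation TSV needs two columns (probe_id, gene_symbol)")
    probes, genes = frame.iloc[:, 0], frame.iloc[:, 1]
    if probes.duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    return dict(zip(probes, genes))


def write_provenance(records, path) -> None:
    Path(path).write_text(json.dumps(records, indent=2, default=str) + "\n", encoding="utf-8")
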