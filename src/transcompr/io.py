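"""Core data containers and file formats.

Everything the pipeline touches on disk is plain text: tab-delimited
gene-by-sample expression matrices with a companion per-sample metadata
table, GMT gene-set collections, a two/three-column homolog map, and a
gene annotation table carrying a secreted-protein flag.

Gene identifiers are opaque strings matched exactly; alias resolution is
the job of whoever produced the tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_METADATA = ("age", "sex", "disease_label")


class FormatError(ValueError):
    """Malformed input file or matrix."""


class MetadataError(ValueError):
    """Sample metadata missing or inconsistent with the expression matrix."""


@dataclass
class ExpressionStudy:
    """One species' gene-by-sample expression matrix plus sample metadata.

    Parameters
    ----------
    values
        Genes x samples matrix of log-scale intensities (rows: gene or
        probe identifiers, columns: sample identifiers).
    metadata
        Per-sample records indexed by sample id. Must carry ``age``,
        ``sex`` and ``disease_label``; ``disease_code`` is optional
        (human studies may only have labels).
    species
        ``"human"`` or ``"mouse"``.
    partner_ids
        After homolog filtering, the paired gene id in the other species
        for each retained row (index: this study's gene ids).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    species: str = "human"
    partner_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicated gene/probe ids: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicated sample ids: {list(dupes[:5])}")
        if self.values.isna().to_numpy().any():
            raise FormatError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise MetadataError(f"samples absent from metadata: {missing[:5]}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise MetadataError(f"metadata lacks required column {col!r}")
        meta = self.metadata.loc[self.values.columns]
        for col in REQUIRED_METADATA:
            if meta[col].isna().any():
                bad = meta.index[meta[col].isna()].tolist()
                raise MetadataError(f"missing {col!r} for samples {bad[:5]}")
        self.metadata = meta

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(
        self, genes: Iterable[str], partner_ids: pd.Series | None = None
    ) -> "ExpressionStudy":
        genes = list(genes)
        return ExpressionStudy(
            values=self.values.loc[genes],
            metadata=self.metadata,
            species=self.species,
            partner_ids=partner_ids,
        )


@dataclass
class HomologMap:
    """Human-to-mouse gene pairing.

    ``pairs`` has columns ``human``, ``mouse`` and a derived boolean
    ``one_to_one``; a pair is one-to-one when its human gene appears
    exactly once on the human side and its mouse gene exactly once on
    the mouse side. Restricted to one-to-one pairs the map is a
    bijection between its domain and range.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("human", "mouse"):
            if col not in self.pairs.columns:
                raise FormatError(f"homolog map lacks column {col!r}")
        pairs = self.pairs.reset_index(drop=True).copy()
        h_dup = pairs["human"].duplicated(keep=False)
        m_dup = pairs["mouse"].duplicated(keep=False)
        pairs["one_to_one"] = ~(h_dup | m_dup)
        self.pairs = pairs

    @classmethod
    def from_pairs(cls, human: Iterable[str], mouse: Iterable[str]) -> "HomologMap":
        return cls(pd.DataFrame({"human": list(human), "mouse": list(mouse)}))

    @classmethod
    def identity(cls, gene_ids: Iterable[str]) -> "HomologMap":
        ids = list(gene_ids)
        return cls.from_pairs(ids, ids)

    def one_to_one_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["one_to_one"]].reset_index(drop=True)

    def human_to_mouse(self) -> dict[str, str]:
        oto = self.one_to_one_pairs()
        return dict(zip(oto["human"], oto["mouse"]))

    def mouse_to_human(self) -> dict[str, str]:
        oto = self.one_to_one_pairs()
        return dict(zip(oto["mouse"], oto["human"]))


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


@dataclass
class AnnotationTable:
    """Per-gene annotation, currently a secreted-protein flag plus notes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError("duplicated gene ids in annotation table")
        if "secreted" not in self.table.columns:
            raise FormatError("annotation table lacks 'secreted' column")
        self.table = self.table.assign(secreted=self.table["secreted"].astype(bool))
        if "notes" not in self.table.columns:
            self.table["notes"] = ""

    def covers(self, gene: str) -> bool:
        return gene in self.table.index

    def is_secreted(self, gene: str) -> bool:
        return bool(self.table.loc[gene, "secreted"])


# ---------------------------------------------------------------------------
# readers / writers


def _read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    return meta


def read_expression(path, metadata_path, species: str = "human") -> ExpressionStudy:
    """Read a tab-delimited genes-x-samples matrix and its metadata table.

    The matrix has a header row of sample ids and a first column of
    gene/probe ids. Every sample column must have a metadata record.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"duplicated sample column id in {path}")
    try:
        values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if values.shape[1] != len(sample_ids):
        raise FormatError(f"header/body dimension mismatch in {path}")
    values.columns = sample_ids
    values.index = values.index.astype(str)
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        raise FormatError(f"non-numeric values in expression matrix {path}")
    return ExpressionStudy(values=values, metadata=_read_metadata(metadata_path), species=species)


def write_expression(study: ExpressionStudy, path, metadata_path=None) -> None:
    # %.17g round-trips IEEE doubles exactly
    study.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")
    if metadata_path is not None:
        study.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, description, members")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_homolog_map(path) -> HomologMap:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"human", "mouse"}.issubset(table.columns):
        if table.shape[1] < 2:
            raise FormatError(f"homolog map {path} needs >= 2 columns")
        table = table.rename(
            columns={table.columns[0]: "human", table.columns[1]: "mouse"}
        )
    if table[["human", "mouse"]].isna().any().any():
        raise FormatError(f"homolog map {path} has blank entries")
    return HomologMap(table[["human", "mouse"]])


def write_homolog_map(hmap: HomologMap, path) -> None:
    hmap.pairs[["human", "mouse"]].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> AnnotationTable:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if "secreted" not in table.columns:
        raise FormatError(f"annotation table {path} lacks 'secreted' column")
    truthy = {"1", "true", "yes", "y", "t"}
    if table["secreted"].dtype == object:
        table["secreted"] = (
            table["secreted"].astype(str).str.strip().str.lower().isin(truthy)
        )
    return AnnotationTable(table)


def write_annotation(annot: AnnotationTable, path) -> None:
    out = annot.table.copy()
    out["secreted"] = out["secreted"].astype(int)
    out.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# probe collapse


def collapse_probes(study: ExpressionStudy, probe_to_gene: Mapping[str, str]) -> ExpressionStudy:
    """Collapse probe-level rows to one row per gene by per-sample median.

    Probes absent from the mapping are dropped (the count is logged).
    Output rows are sorted by gene id, which makes the operation
    idempotent when re-applied with an identity mapping.
    """
    mapped = [p for p in study.gene_ids if p in probe_to_gene]
    n_dropped = study.n_genes - len(mapped)
    if not mapped:
        raise FormatError("no probes map to any gene")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = study.values.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene_id")
    collapsed = sub.groupby(genes, sort=True).median()
    return ExpressionStudy(values=collapsed, metadata=study.metadata, species=study.species)
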