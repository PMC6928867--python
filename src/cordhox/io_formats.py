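"""Readers and writers for the file formats the pipeline touches.

All gene identity in this package is by normalized HGNC-style symbol
(uppercase, whitespace-stripped); there is no identifier-mapping service.
Every ingestion path normalizes exactly once, so re-reading written output
is a no-op.

Formats owned here: GMT gene-set libraries, expression TSV matrices
(genes x labeled columns), a six-column protein-interaction TSV dialect,
and plain-text transcription-factor catalogs.  GAF ingestion lives in
:mod:`cordhox.go_cooccurrence`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("cordhox")

HUMAN_TAXID = "9606"


class FormatError(ValueError):
    """A file does not conform to its declared format; message locates the problem."""


# ---------------------------------------------------------------------------
# Gene symbols
# ---------------------------------------------------------------------------

def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip whitespace, uppercase.

    Idempotent; raises ``ValueError`` on empty input.
    """
    s = symbol.strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


def normalize_symbols(symbols: Iterable[str]) -> frozenset[str]:
    """Normalize an iterable of symbols into a duplicate-free frozen set."""
    return frozenset(normalize_symbol(s) for s in symbols)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetLibrary:
    """Named gene sets (tissue signatures, annotation term->gene libraries).

    ``entries`` maps set name -> frozenset of normalized symbols; insertion
    order is preserved.  Sets may overlap; names are unique by construction.
    """

    entries: dict[str, frozenset[str]]
    source_tag: str = ""

    def __getitem__(self, name: str) -> frozenset[str]:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(f"unknown gene set {name!r}; available: {sorted(self.entries)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries


@dataclass(frozen=True)
class ExpressionColumn:
    """One labeled column of an expression matrix."""

    label: str
    group: str = ""
    n_samples: int = 1


@dataclass
class ExpressionMatrix:
    """Genes x labeled columns of non-negative expression values.

    ``values`` is a pandas DataFrame indexed by normalized gene symbol with
    one column per :class:`ExpressionColumn` label.  ``unit`` records the
    abundance unit (TPM, FPKM, ...) so downstream thresholds are meaningful.
    """

    values: pd.DataFrame
    unit: str = "TPM"
    columns: list[ExpressionColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.columns:
            self.columns = [ExpressionColumn(label=str(c)) for c in self.values.columns]
        labels = [c.label for c in self.columns]
        if list(self.values.columns) != labels:
            raise ValueError("column metadata does not match matrix columns")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows after normalization: {dupes}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values are not allowed")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def value(self, gene: str, label: str) -> float:
        return float(self.values.at[normalize_symbol(gene), label])


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected protein-protein interaction, endpoints lexicographic."""

    a: str
    b: str
    species_taxid: str = HUMAN_TAXID
    published: bool = True
    system: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass(frozen=True)
class Interactome:
    """A cleaned set of undirected interaction edges.

    Edges are stored with endpoints ordered lexicographically, so the edge
    set is invariant to input ordering; self-edges are excluded upstream.
    """

    edges: frozenset[InteractionEdge]

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for e in self.edges:
            adj.setdefault(e.a, set()).add(e.b)
            adj.setdefault(e.b, set()).add(e.a)
        return adj


@dataclass(frozen=True)
class TFCatalog:
    """Catalog of human transcription-factor gene symbols.

    ``total_count`` is the universe size used by enrichment statistics and
    always equals ``len(members)``.
    """

    members: frozenset[str]

    @property
    def total_count(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members


def make_edge(a: str, b: str, species_taxid: str = HUMAN_TAXID,
              published: bool = True, system: str = "") -> InteractionEdge:
    """Build a lexicographically ordered edge from two (raw) symbols."""
    na, nb = normalize_symbol(a), normalize_symbol(b)
    if na == nb:
        raise ValueError(f"self-edge {na}")
    if na > nb:
        na, nb = nb, na
    return InteractionEdge(na, nb, species_taxid, published, system)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source_tag: str = "") -> GeneSetLibrary:
    """Read a GMT library: one set per line, ``name<TAB>description<TAB>members...``.

    Empty member fields are skipped; duplicate members collapse; duplicate
    set names or lines with fewer than three fields are format errors.
    """
    path = Path(path)
    entries: dict[str, frozenset[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(parts)}")
            name = parts[0].strip()
            if not name:
                raise FormatError(f"{path}:{lineno}: empty set name")
            if name in entries:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(
                normalize_symbol(m) for m in parts[2:] if m.strip())
            entries[name] = members
    return GeneSetLibrary(entries=entries, source_tag=source_tag or str(path))


def write_gmt(library: GeneSetLibrary, path: str | Path) -> Path:
    """Write a library in GMT form; members sorted for deterministic output."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for name, members in library.entries.items():
            desc = library.source_tag or "na"
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, unit: str = "TPM",
                        columns: Sequence[ExpressionColumn] | None = None) -> ExpressionMatrix:
    """Read a genes-x-columns expression table.

    First header field names the gene column; remaining header fields are
    column labels.  Cells must parse as non-negative reals; violations are
    reported with (gene, column) coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty expression table")
    df.index = [normalize_symbol(g) for g in df.index]
    if pd.Index(df.index).has_duplicates:
        dupes = pd.Index(df.index)[pd.Index(df.index).duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows after normalization: {dupes}")
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for gene, cell in df[col].items():
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise FormatError(f"{path}: non-numeric cell at ({gene}, {col}): {cell!r}")
            if v < 0:
                raise FormatError(f"{path}: negative value at ({gene}, {col}): {v}")
            parsed.at[gene, col] = v
    cols = list(columns) if columns is not None else None
    return ExpressionMatrix(values=parsed, unit=unit, columns=cols or [])


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path,
                         gene_header: str = "gene") -> Path:
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = gene_header
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Interactome TSV (reduced six-column dialect)
# ---------------------------------------------------------------------------

REQUIRED_INTERACTOME_COLUMNS = (
    "interactor_a", "interactor_b", "taxid_a", "taxid_b", "publication_id", "system",
)


def read_interactome(path: str | Path, species_taxid: str = HUMAN_TAXID,
                     column_map: Mapping[str, str] | None = None) -> Interactome:
    """Read a six-column interaction table and apply the cleaning filters.

    Rows are dropped when either endpoint's taxid differs from
    ``species_taxid``, when the publication field is empty (unpublished
    interactions), or when the two endpoints coincide (self-interactions).
    Filter counts are logged.  ``column_map`` renames file columns onto the
    required dialect, for pre-projected exports with other headers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_INTERACTOME_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    n_total = len(df)
    taxid = str(species_taxid)
    species_ok = (df["taxid_a"].str.strip() == taxid) & (df["taxid_b"].str.strip() == taxid)
    published_ok = df["publication_id"].str.strip() != ""
    kept = df[species_ok & published_ok]
    n_species = int((~species_ok).sum())
    n_unpub = int((species_ok & ~published_ok).sum())

    edges: set[InteractionEdge] = set()
    n_self = 0
    for row in kept.itertuples(index=False):
        a = normalize_symbol(row.interactor_a)
        b = normalize_symbol(row.interactor_b)
        if a == b:
            n_self += 1
            continue
        if a > b:
            a, b = b, a
        edges.add(InteractionEdge(a, b, taxid, True, row.system.strip()))
    logger.info(
        "read_interactome(%s): %d rows; dropped %d non-%s, %d unpublished, %d self-edges; %d edges kept",
        path.name, n_total, n_species, taxid, n_unpub, n_self, len(edges))
    return Interactome(edges=frozenset(edges))


def write_interactome(net: Interactome, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(REQUIRED_INTERACTOME_COLUMNS) + "\n")
        for e in sorted(net.edges, key=lambda e: (e.a, e.b, e.system)):
            pub = "curated" if e.published else ""
            fh.write(f"{e.a}\t{e.b}\t{e.species_taxid}\t{e.species_taxid}\t{pub}\t{e.system}\n")
    return path


# ---------------------------------------------------------------------------
# TF catalog (plain list)
# ---------------------------------------------------------------------------

def read_tf_catalog(path: str | Path) -> TFCatalog:
    """Read a one-symbol-per-line transcription-factor catalog."""
    path = Path(path)
    members: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                members.add(normalize_symbol(line))
    return TFCatalog(members=frozenset(members))


def write_tf_catalog(catalog: TFCatalog, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(sorted(catalog.members)) + "\n", encoding="utf-8")
    return path


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a plain newline-separated gene list into a normalized set."""
    return read_tf_catalog(path).members
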