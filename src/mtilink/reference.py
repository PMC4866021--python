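"""Loading and harmonizing validated miRNA-target interaction (MTI) sources.

Four source databases of experimentally validated interactions (TarBase,
miRTarBase, miRecords, starBase) are consumed in a common interchange TSV
schema.  Each record carries the miRNA (as an identifier or, TarBase-style,
as a miRBase accession), the target gene symbol, the interaction species,
the validation methods, and — for starBase — the number of supporting
CLIP-Seq experiments.

Because the sources name targets inconsistently, every target symbol is
mapped onto UniProt accessions (via gene symbol, synonyms and
cross-references), either species-specifically or species-agnostically;
the agnostic mode pulls in homologous targets across organisms, which is
what makes the pipeline usable for organisms without curated resources.
Cross-database agreement is then counted per (miRNA key, accession) pair
and encoded as a 4-bit occurrence string.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .identifiers import MatchPolicy, MirnaParseError, cluster_key, parse_mirna_id

__all__ = [
    "SOURCE_DBS",
    "MtiRecord",
    "UniprotEntry",
    "UniprotTable",
    "LinkedMti",
    "SchemaError",
    "LoadReport",
    "HarmonizeResult",
    "load_db",
    "load_uniprot_table",
    "load_accession_table",
    "resolve_accession",
    "resolve_mirna_ids",
    "map_symbol_to_uniprot",
    "harmonize",
]

#: Fixed source order; it defines the bit order of occurrence strings.
SOURCE_DBS = ("tarbase", "mirtarbase", "mirecords", "starbase")

_DB_COLUMNS = [
    "source_db", "mirna_id", "mirbase_acc", "target_symbol",
    "species", "methods", "clip_support",
]
_MAPPING_COLUMNS = [
    "accession", "gene_symbol", "synonyms", "species",
    "protein_name", "go_terms", "cross_references",
]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass(frozen=True)
class MtiRecord:
    """One validated interaction from one source database."""

    source_db: str
    mirna_raw: str
    mirbase_acc: str | None
    target_symbol: str
    species: str
    methods: frozenset[str]
    clip_support: int = 0


@dataclass(frozen=True)
class UniprotEntry:
    accession: str
    gene_symbol: str
    synonyms: frozenset[str]
    species: str
    protein_name: str = ""
    go_terms: frozenset[str] = frozenset()
    cross_references: frozenset[str] = frozenset()


@dataclass(frozen=True)
class LinkedMti:
    """A harmonized interaction: one (miRNA key, UniProt accession) pair.

    ``sources`` is the 4-character occurrence string over
    (tarbase, mirtarbase, mirecords, starbase); "1" marks a source
    database reporting the pair.
    """

    mirna_key: str
    accession: str
    species: str
    sources: str

    def popcount(self) -> int:
        return self.sources.count("1")


@dataclass
class LoadReport:
    """Per-file load bookkeeping: surviving records plus rejected rows."""

    records: list[MtiRecord]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _split_multi(value: str) -> frozenset[str]:
    return frozenset(v.strip() for v in value.split(";") if v.strip())


def load_db(path: str | Path, source_db: str) -> LoadReport:
    """Load one interchange TSV of validated interactions.

    Every well-formed row yields one :class:`MtiRecord`.  Malformed rows
    (empty target symbol, no miRNA information, non-integer or negative
    clip support, clip support on a non-starBase row, mismatched source
    name) are counted and reported, not fatal.  A missing mandatory
    column aborts with a :class:`SchemaError` naming the column.
    """
    if source_db not in SOURCE_DBS:
        raise ValueError(f"unknown source database {source_db!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _DB_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")

    records: list[MtiRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        reason = None
        clip = 0
        if row.source_db != source_db:
            reason = f"source_db {row.source_db!r} != {source_db!r}"
        elif not row.target_symbol.strip():
            reason = "empty target_symbol"
        elif not row.mirna_id.strip() and not row.mirbase_acc.strip():
            reason = "no miRNA identifier or accession"
        elif not row.species.strip():
            reason = "empty species"
        else:
            try:
                clip = int(row.clip_support) if row.clip_support.strip() else 0
            except ValueError:
                reason = f"non-integer clip_support {row.clip_support!r}"
            else:
                if clip < 0:
                    reason = "negative clip_support"
                elif clip > 0 and source_db != "starbase":
                    reason = "clip_support set outside starbase"
        if reason is not None:
            rejected.append((i, reason))
            continue
        records.append(MtiRecord(
            source_db=source_db,
            mirna_raw=row.mirna_id.strip(),
            mirbase_acc=row.mirbase_acc.strip() or None,
            target_symbol=row.target_symbol.strip(),
            species=row.species.strip(),
            methods=_split_multi(row.methods),
            clip_support=clip,
        ))
    return LoadReport(records=records, rejected=rejected)


class UniprotTable:
    """Symbol -> UniProt lookup over entries, synonyms and cross-references.

    Matching is exact token equality after case folding; no fuzzy matching,
    which would silently inflate homology hits.
    """

    def __init__(self, entries: Sequence[UniprotEntry]):
        seen: dict[str, UniprotEntry] = {}
        for e in entries:
            if e.accession in seen:
                raise ValueError(f"duplicate accession {e.accession}")
            seen[e.accession] = e
        self.entries: dict[str, UniprotEntry] = seen
        self._by_token: dict[str, list[UniprotEntry]] = defaultdict(list)
        for e in entries:
            tokens = {e.gene_symbol, *e.synonyms, *e.cross_references}
            for tok in tokens:
                if tok:
                    self._by_token[tok.lower()].append(e)

    def lookup(self, symbol: str, species: str | None = None) -> set[str]:
        hits = self._by_token.get(symbol.strip().lower(), [])
        if species is None:
            return {e.accession for e in hits}
        return {e.accession for e in hits if e.species == species}

    def get(self, accession: str) -> UniprotEntry | None:
        return self.entries.get(accession)

    def __len__(self) -> int:
        return len(self.entries)


def load_uniprot_table(path: str | Path) -> UniprotTable:
    """Load the symbol/synonym/cross-reference -> accession mapping TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _MAPPING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    entries = [
        UniprotEntry(
            accession=row.accession,
            gene_symbol=row.gene_symbol,
            synonyms=_split_multi(row.synonyms),
            species=row.species,
            protein_name=row.protein_name,
            go_terms=_split_multi(row.go_terms),
            cross_references=_split_multi(row.cross_references),
        )
        for row in df.itertuples(index=False)
    ]
    return UniprotTable(entries)


def load_accession_table(path: str | Path) -> dict[str, str]:
    """Load the miRBase accession -> mature identifier table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "mirna_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    return dict(zip(df["accession"], df["mirna_id"]))


def resolve_accession(mirbase_acc: str, acc_table: Mapping[str, str]) -> str | None:
    """Map a miRBase accession to its mature identifier; None if unmapped."""
    return acc_table.get(mirbase_acc)


def resolve_mirna_ids(
    records: Iterable[MtiRecord], acc_table: Mapping[str, str]
) -> tuple[list[MtiRecord], int]:
    """Fill miRNA identifiers from miRBase accessions where needed.

    Records that carry only an accession (TarBase-style) are resolved via
    the table; unmappable ones are dropped and counted.
    """
    out: list[MtiRecord] = []
    dropped = 0
    for rec in records:
        if rec.mirna_raw:
            out.append(rec)
            continue
        ident = resolve_accession(rec.mirbase_acc or "", acc_table)
        if ident is None:
            dropped += 1
            continue
        out.append(MtiRecord(
            source_db=rec.source_db,
            mirna_raw=ident,
            mirbase_acc=rec.mirbase_acc,
            target_symbol=rec.target_symbol,
            species=rec.species,
            methods=rec.methods,
            clip_support=rec.clip_support,
        ))
    return out, dropped


def map_symbol_to_uniprot(
    symbol: str, species: str, agnostic: bool, table: UniprotTable
) -> set[str]:
    """Map one target symbol to UniProt accessions.

    Species-specific mode restricts hits to entries of the record's
    species; agnostic mode ignores species membership, returning every
    accession whose symbol, synonym or cross-reference equals the query
    (case-insensitive) — the homology route.  Empty set when nothing
    matches.
    """
    return table.lookup(symbol, None if agnostic else species)


@dataclass
class HarmonizeResult:
    linked: list[LinkedMti]
    n_unmapped_symbols: int
    n_unparsed_mirnas: int
    #: distinct (source_db, mirna_key, accession) mapping events that
    #: survived symbol mapping; equals the popcount sum over ``linked``.
    n_mapping_events: int


def harmonize(
    records: Iterable[MtiRecord],
    policy: MatchPolicy,
    agnostic: bool,
    table: UniprotTable,
) -> HarmonizeResult:
    """Collapse records into occurrence-annotated (miRNA key, accession) pairs.

    Each record's symbol is mapped to accessions; each (record, accession)
    pair contributes its source bit to exactly one :class:`LinkedMti`
    keyed by (cluster key under ``policy``, accession).  Database
    occurrence is counted after UniProt mapping so that cross-database
    agreement is measured on the harmonized identifier, not on raw
    symbols.  Records whose symbol maps to nothing, or whose miRNA name
    does not parse, are dropped and counted.
    """
    bits: dict[tuple[str, str], set[str]] = defaultdict(set)
    pair_species: dict[tuple[str, str], str] = {}
    n_unmapped = 0
    n_unparsed = 0
    for rec in records:
        try:
            ident = parse_mirna_id(rec.mirna_raw)
        except MirnaParseError:
            n_unparsed += 1
            continue
        key = cluster_key(ident, policy)
        accs = map_symbol_to_uniprot(rec.target_symbol, rec.species, agnostic, table)
        if not accs:
            n_unmapped += 1
            continue
        for acc in accs:
            pair = (key, acc)
            bits[pair].add(rec.source_db)
            entry = table.get(acc)
            pair_species[pair] = entry.species if entry else rec.species
    linked = [
        LinkedMti(
            mirna_key=key,
            accession=acc,
            species=pair_species[(key, acc)],
            sources="".join("1" if db in dbs else "0" for db in SOURCE_DBS),
        )
        for (key, acc), dbs in sorted(bits.items())
    ]
    n_events = sum(len(dbs) for dbs in bits.values())
    return HarmonizeResult(
        linked=linked,
        n_unmapped_symbols=n_unmapped,
        n_unparsed_mirnas=n_unparsed,
        n_mapping_events=n_events,
    )
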