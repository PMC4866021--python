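"""Assembly of per-miRNA target sets and the tabular result views.

After filtering, the surviving (miRNA key, accession) pairs are presented
from several angles: per-miRNA target sets, an interaction matrix whose
cells hold the 4-bit database-occurrence strings, a per-target
information table carrying the UniProt annotation, a set-overlap matrix,
and the per-stage count table behind the bar-graph overview.  All views
are derived from the same relation and stay pairwise consistent.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import LinkedMti, UniprotTable

__all__ = [
    "MtiSet",
    "build_sets",
    "build_matrix",
    "build_info_table",
    "overlap_heatmap_matrix",
    "rank_sets_by_size",
    "step_counts",
]


@dataclass
class MtiSet:
    """One miRNA key with its set of target accessions."""

    mirna_key: str
    targets: set[str]
    occurrence: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.targets)


def build_sets(linked: Iterable[LinkedMti]) -> list[MtiSet]:
    """Group pairs into one target set per distinct miRNA key."""
    by_key: dict[str, MtiSet] = {}
    for mti in linked:
        s = by_key.setdefault(mti.mirna_key, MtiSet(mti.mirna_key, set()))
        s.targets.add(mti.accession)
        s.occurrence[mti.accession] = mti.sources
    return [by_key[k] for k in sorted(by_key)]


def build_matrix(linked: Sequence[LinkedMti]) -> pd.DataFrame:
    """Interaction matrix: rows = accessions, columns = miRNA keys.

    A cell holds the pair's 4-character occurrence string, or "" when the
    pair is absent; non-empty cells are in bijection with the pairs.
    """
    accs = sorted({m.accession for m in linked})
    keys = sorted({m.mirna_key for m in linked})
    df = pd.DataFrame("", index=pd.Index(accs, name="accession"), columns=keys)
    for mti in linked:
        df.at[mti.accession, mti.mirna_key] = mti.sources
    return df


def build_info_table(
    linked: Sequence[LinkedMti], table: UniprotTable
) -> pd.DataFrame:
    """Per-target annotation: one row per accession in the result.

    Lists the interacting miRNA keys plus gene symbol, synonyms, species,
    protein name and GO terms from the mapping table.  An accession
    missing from the table (defensive only) yields a row with blanks and
    a warning.
    """
    keys_by_acc: dict[str, set[str]] = defaultdict(set)
    for mti in linked:
        keys_by_acc[mti.accession].add(mti.mirna_key)
    rows = []
    for acc in sorted(keys_by_acc):
        entry = table.get(acc)
        if entry is None:
            warnings.warn(f"accession {acc} absent from mapping table")
        rows.append({
            "accession": acc,
            "mirna_keys": ";".join(sorted(keys_by_acc[acc])),
            "gene_symbol": entry.gene_symbol if entry else "",
            "synonyms": ";".join(sorted(entry.synonyms)) if entry else "",
            "species": entry.species if entry else "",
            "protein_name": entry.protein_name if entry else "",
            "go_terms": ";".join(sorted(entry.go_terms)) if entry else "",
        })
    return pd.DataFrame(rows, columns=[
        "accession", "mirna_keys", "gene_symbol", "synonyms",
        "species", "protein_name", "go_terms",
    ])


def overlap_heatmap_matrix(
    sets: Sequence[MtiSet],
    leading_edges: Mapping[str, set[str]] | None = None,
    metric: str = "jaccard",
) -> pd.DataFrame:
    """Pairwise target overlap between sets (symmetric, diagonal 1).

    The default metric is the Jaccard index |A∩B| / |A∪B|;
    ``metric="intersection-count"`` reports raw shared-member counts
    (diagonal = set size).  When the enrichment analysis ran, its leading
    edges are substituted for the full sets; an empty leading edge gives
    a zero row/column (diagonal excepted) with a warning.
    """
    if metric not in ("jaccard", "intersection-count"):
        raise ValueError(f"unknown overlap metric {metric!r}")
    members: dict[str, set[str]] = {}
    for s in sets:
        if leading_edges is not None:
            sub = leading_edges.get(s.mirna_key, set())
            if not sub:
                warnings.warn(f"empty leading edge for {s.mirna_key}")
            members[s.mirna_key] = sub
        else:
            members[s.mirna_key] = s.targets
    keys = sorted(members)
    df = pd.DataFrame(0.0, index=pd.Index(keys, name="mirna_key"), columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i:]:
            inter = len(members[a] & members[b])
            if metric == "jaccard":
                union = len(members[a] | members[b])
                val = inter / union if union else (1.0 if a == b else 0.0)
            else:
                val = float(inter)
            df.at[a, b] = val
            df.at[b, a] = val
        if metric == "jaccard":
            df.at[a, a] = 1.0
    return df


def rank_sets_by_size(sets: Sequence[MtiSet]) -> pd.DataFrame:
    """Size-ranked set table, used when no enrichment analysis ran.

    Descending target count; ties broken lexicographically by key.
    """
    rows = sorted(sets, key=lambda s: (-s.size, s.mirna_key))
    return pd.DataFrame(
        [{"mirna_key": s.mirna_key, "n_targets": s.size} for s in rows],
        columns=["mirna_key", "n_targets"],
    )


def step_counts(
    stages: Sequence[tuple[str, int | None, int | None]]
) -> pd.DataFrame:
    """Bar-graph table: miRNA and interaction counts per pipeline stage.

    ``None`` marks a not-applicable count (e.g. miRNA input rows when no
    miRNA list was supplied) and is rendered as "NA".
    """
    rows = [
        {
            "stage": name,
            "n_mirnas": "NA" if n_mir is None else n_mir,
            "n_mtis": "NA" if n_mti is None else n_mti,
        }
        for name, n_mir, n_mti in stages
    ]
    return pd.DataFrame(rows, columns=["stage", "n_mirnas", "n_mtis"])
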