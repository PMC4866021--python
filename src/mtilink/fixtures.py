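"""Synthetic reference databases and ranked lists with planted structure.

Every pipeline stage is testable without downloads: this module writes
interchange TSVs for the four interaction sources, a symbol→UniProt
mapping table and a miRBase-style accession table, together with a
ground-truth manifest recording every planted quantity (occurrence
strings, filter-survivor counts, per-file row composition, symbol
fan-outs).  Identifier shapes mimic real-world conventions ("hsa"
species codes, "P#####"-style accessions) without claiming real
identities; no attempt is made to mimic the real databases' species or
method distributions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .reference import SOURCE_DBS

__all__ = ["FixtureSpec", "RankedSpec", "generate_reference", "generate_ranked"]

SPECIES_POOL = ("hsa", "mmu", "rno", "dre", "gga", "cel", "dme", "xla")
METHOD_VOCAB = ("Reporter assay", "Western blot", "qPCR",
                "Microarray", "NGS", "CLIP-Seq")


class FixtureError(ValueError):
    """The requested fixture is infeasible."""


@dataclass
class FixtureSpec:
    """Parameters of a synthetic reference-database bundle.

    ``occurrence_histogram`` maps database-occurrence counts (1-4) to the
    number of (miRNA, target) pairs planted with exactly that many source
    databases.  ``fanout_symbols`` symbols additionally receive mapping
    entries in every species, exercising the species-agnostic homology
    route.  ``n_unmappable_accessions`` plants TarBase rows whose
    miRBase accession resolves to nothing; ``n_malformed`` plants rows
    the loader must reject; ``duplicate_records_per_db`` re-emits
    existing rows so raw row counts exceed pair counts.
    """

    n_mirnas: int = 30
    n_targets: int = 60
    n_species: int = 3
    occurrence_histogram: dict[int, int] = field(
        default_factory=lambda: {1: 30, 2: 12, 3: 5, 4: 1})
    fanout_symbols: int = 0
    n_unmappable_accessions: int = 0
    n_malformed: int = 0
    duplicate_records_per_db: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mirnas, self.n_targets, self.n_species) <= 0:
            raise FixtureError("counts must be positive")
        if self.n_species > len(SPECIES_POOL):
            raise FixtureError(f"at most {len(SPECIES_POOL)} species supported")
        for k, v in self.occurrence_histogram.items():
            if not 1 <= int(k) <= 4 or v < 0:
                raise FixtureError("histogram keys in [1,4], counts >= 0")
        total = sum(self.occurrence_histogram.values())
        if total > self.n_mirnas * self.n_targets:
            raise FixtureError(
                f"{total} pairs requested but only "
                f"{self.n_mirnas * self.n_targets} pairs are achievable")
        if self.fanout_symbols > self.n_targets:
            raise FixtureError("fanout_symbols exceeds n_targets")
        unknown = set(self.duplicate_records_per_db) - set(SOURCE_DBS)
        if unknown:
            raise FixtureError(f"unknown databases: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        spec = cls(**{k: v for k, v in data.items()
                      if k in cls.__dataclass_fields__})
        spec.occurrence_histogram = {
            int(k): int(v) for k, v in spec.occurrence_histogram.items()}
        return spec


def generate_reference(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the four source TSVs, mapping tables, and the truth manifest.

    Deterministic: the same spec (including seed) yields byte-identical
    files.  Returns the manifest (also written as ``manifest.json``).
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    species = list(SPECIES_POOL[: spec.n_species])

    mirnas = []
    for i in range(spec.n_mirnas):
        sp = species[i % len(species)]
        arm = ("3p", "5p")[i % 2]
        core = f"miR-{100 + i}"
        mirnas.append({
            "mirna_id": f"{sp}-{core}-{arm}",
            "mirbase_acc": f"MIMAT{i:07d}",
            "core": core, "species": sp, "arm": arm,
        })

    # mapping table: one primary entry per symbol; fan-out symbols get an
    # extra entry per remaining species (agnostic-mode homologs)
    targets = []
    mapping_rows = []
    fanout: dict[str, dict[str, str]] = {}
    for j in range(spec.n_targets):
        sp = species[j % len(species)]
        symbol = f"GENE{j}"
        acc = f"P{10000 + j:05d}"
        targets.append({"symbol": symbol, "accession": acc, "species": sp})
        fanout[symbol] = {sp: acc}
        mapping_rows.append({
            "accession": acc, "gene_symbol": symbol,
            "synonyms": f"SYN{j}A;SYN{j}B", "species": sp,
            "protein_name": f"Protein {j}",
            "go_terms": f"GO:{7000000 + j};GO:{8000000 + j}",
            "cross_references": f"XREF{j}",
        })
        if j < spec.fanout_symbols:
            for k, other in enumerate(s for s in species if s != sp):
                acc2 = f"Q{j:02d}{k:02d}0"
                fanout[symbol][other] = acc2
                mapping_rows.append({
                    "accession": acc2, "gene_symbol": symbol,
                    "synonyms": "", "species": other,
                    "protein_name": f"Protein {j} homolog",
                    "go_terms": f"GO:{7000000 + j}",
                    "cross_references": "",
                })

    # planted pairs with their database-occurrence assignments
    total_pairs = sum(spec.occurrence_histogram.values())
    flat = rng.choice(spec.n_mirnas * spec.n_targets, size=total_pairs,
                      replace=False)
    popcounts = [k for k in sorted(spec.occurrence_histogram)
                 for _ in range(spec.occurrence_histogram[k])]
    combos = {k: list(itertools.combinations(SOURCE_DBS, k))
              for k in range(1, 5)}
    pairs = []
    rows_by_db: dict[str, list[dict]] = {db: [] for db in SOURCE_DBS}
    for flat_idx, pc in zip(flat, popcounts):
        mi, tj = divmod(int(flat_idx), spec.n_targets)
        mirna, target = mirnas[mi], targets[tj]
        dbs = combos[pc][int(rng.integers(len(combos[pc])))]
        for db in dbs:
            n_m = int(rng.integers(1, 3))
            methods = list(rng.choice(METHOD_VOCAB[:5], size=n_m,
                                      replace=False))
            clip = 0
            if db == "starbase":
                methods = ["CLIP-Seq"]
                clip = int(rng.integers(1, 6))
            rows_by_db[db].append({
                "source_db": db,
                "mirna_id": "" if db == "tarbase" else mirna["mirna_id"],
                "mirbase_acc": mirna["mirbase_acc"] if db == "tarbase" else "",
                "target_symbol": target["symbol"],
                "species": target["species"],
                "methods": ";".join(methods),
                "clip_support": str(clip),
            })
        pairs.append({
            "mirna_id": mirna["mirna_id"],
            "accession": target["accession"],
            "symbol": target["symbol"],
            "species": target["species"],
            "sources": "".join("1" if db in dbs else "0"
                               for db in SOURCE_DBS),
        })

    # duplicate rows: same pair re-reported within one database
    for db, n_dup in spec.duplicate_records_per_db.items():
        if n_dup and not rows_by_db[db]:
            raise FixtureError(f"cannot duplicate rows of empty {db}")
        for d in range(n_dup):
            base = dict(rows_by_db[db][d % len(rows_by_db[db])])
            base["methods"] = METHOD_VOCAB[5] if db != "starbase" else "CLIP-Seq"
            rows_by_db[db].append(base)

    # TarBase rows whose accession resolves to nothing (dropped downstream)
    for u in range(spec.n_unmappable_accessions):
        target = targets[u % len(targets)]
        rows_by_db["tarbase"].append({
            "source_db": "tarbase", "mirna_id": "",
            "mirbase_acc": f"MIMATX{u:06d}",
            "target_symbol": target["symbol"], "species": target["species"],
            "methods": "NGS", "clip_support": "0",
        })

    # malformed rows the loader must reject, cycled over failure kinds
    malformed_by_db = {db: 0 for db in SOURCE_DBS}
    for m in range(spec.n_malformed):
        db = SOURCE_DBS[m % 4]
        mirna, target = mirnas[m % len(mirnas)], targets[m % len(targets)]
        row = {
            "source_db": db,
            "mirna_id": mirna["mirna_id"], "mirbase_acc": "",
            "target_symbol": target["symbol"], "species": target["species"],
            "methods": "qPCR", "clip_support": "0",
        }
        kind = m % 3
        if kind == 0:
            row["target_symbol"] = ""
        elif kind == 1:
            row["clip_support"] = "not-a-number"
        else:
            row["clip_support"] = "3" if db != "starbase" else ""
            if db == "starbase":  # clip cannot be illegal here; break miRNA
                row["mirna_id"] = ""
        malformed_by_db[db] += 1
        rows_by_db[db].append(row)

    per_db = {}
    cols = ["source_db", "mirna_id", "mirbase_acc", "target_symbol",
            "species", "methods", "clip_support"]
    for db in SOURCE_DBS:
        rows = rows_by_db[db]
        order = rng.permutation(len(rows))
        df = pd.DataFrame([rows[i] for i in order], columns=cols)
        df.to_csv(out / f"{db}.tsv", sep="\t", index=False)
        per_db[db] = {
            "rows": len(rows),
            "malformed": malformed_by_db[db],
            "unmappable": (spec.n_unmappable_accessions
                           if db == "tarbase" else 0),
        }

    pd.DataFrame(mapping_rows).to_csv(out / "mapping.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(
        [{"accession": m["mirbase_acc"], "mirna_id": m["mirna_id"]}
         for m in mirnas]
    ).to_csv(out / "accessions.tsv", sep="\t", index=False)

    survivors = {
        k: sum(v for pc, v in spec.occurrence_histogram.items() if pc >= k)
        for k in range(1, 5)
    }
    manifest = {
        "spec": {**asdict(spec),
                 "occurrence_histogram": {
                     str(k): v
                     for k, v in spec.occurrence_histogram.items()}},
        "species": species,
        "mirnas": mirnas,
        "fanout": fanout,
        "pairs": pairs,
        "n_pairs": len(pairs),
        "n_mapping_events": sum(p["sources"].count("1") for p in pairs),
        "survivors_by_min_occurrence": {str(k): v
                                        for k, v in survivors.items()},
        "distinct_mirnas": len({p["mirna_id"] for p in pairs}),
        "distinct_accessions": len({p["accession"] for p in pairs}),
        "per_db": per_db,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


@dataclass
class RankedSpec:
    """Parameters of a synthetic ranked target list with planted sets.

    ``n_planted`` sets have ``loading_fraction`` of their members drawn
    from the top ``top_quantile`` of the list (the enriched signal);
    null sets are drawn uniformly.  With ``loading_fraction`` 0 the
    planted sets are indistinguishable from null — the calibration
    fixture.
    """

    n_ranked: int = 200
    set_size: int = 10
    n_null_sets: int = 20
    n_planted: int = 1
    loading_fraction: float = 1.0
    top_quantile: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RankedSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**{k: v for k, v in data.items()
                      if k in cls.__dataclass_fields__})


def generate_ranked(
    spec: RankedSpec,
    out_dir: str | Path,
    accessions: Sequence[str] | None = None,
) -> dict:
    """Write a ranked TSV plus a manifest of planted and null sets.

    ``accessions`` lets the list reuse identifiers from a reference
    fixture (so the full pipeline can consume it); by default synthetic
    "R#####" accessions are used.  Rank values are positive and strictly
    ordered.  Returns the manifest (also written as
    ``ranked_manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ranked
    if accessions is None:
        accs = [f"R{i:05d}" for i in range(n)]
    else:
        if len(accessions) < n:
            raise FixtureError("not enough accessions supplied")
        accs = list(accessions[:n])
    values = np.sort(rng.exponential(scale=2.0, size=n))[::-1] + \
        np.linspace(0.5, 0.0, n) + 0.1  # strictly decreasing, positive

    n_top = max(1, int(np.ceil(spec.top_quantile * n)))
    k_top = int(round(spec.loading_fraction * spec.set_size))
    if spec.n_planted and (k_top > n_top or spec.set_size - k_top > n - n_top):
        raise FixtureError("top quantile too small for the requested loading")
    sets: dict[str, list[str]] = {}
    for p in range(spec.n_planted):
        top_members = rng.choice(n_top, size=k_top, replace=False)
        rest = rng.choice(np.arange(n_top, n),
                          size=spec.set_size - k_top, replace=False)
        idx = np.concatenate([top_members, rest]).astype(int)
        sets[f"planted_{p}"] = [accs[i] for i in np.sort(idx)]
    for q in range(spec.n_null_sets):
        idx = rng.choice(n, size=spec.set_size, replace=False)
        sets[f"null_{q}"] = [accs[i] for i in np.sort(idx)]

    pd.DataFrame({"accession": accs,
                  "rank_value": np.round(values, 6)}).to_csv(
        out / "ranked.tsv", sep="\t", index=False)
    manifest = {
        "spec": asdict(spec),
        "sets": sets,
        "planted": [f"planted_{p}" for p in range(spec.n_planted)],
        "n_top": n_top,
    }
    (out / "ranked_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
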