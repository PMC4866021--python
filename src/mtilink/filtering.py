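"""User-adjustable selection criteria for validated interactions.

Four knobs control stringency: which source databases participate, the
minimum number of databases that must independently report a pair
(conservation across databases), the species of interest, the accepted
validation methods, and — for starBase — the minimum number of
supporting CLIP-Seq experiments.  Every filter is a pure subset
operation, so filters are idempotent and commute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .identifiers import MatchPolicy, MirnaIdentifier, match, parse_mirna_id
from .reference import SOURCE_DBS, LinkedMti, MtiRecord

__all__ = [
    "FilterConfig",
    "ConfigError",
    "filter_records",
    "filter_occurrence",
    "filter_by_user_mirnas",
    "filter_by_user_targets",
]


class ConfigError(ValueError):
    """Contradictory filter configuration."""


@dataclass(frozen=True)
class FilterConfig:
    """Interaction selection criteria.

    ``methods`` is either the string ``"all"`` or a set of method labels;
    labels are free strings compared case-insensitively after trimming.
    ``starbase_min_clip`` applies to starBase-origin records only.
    """

    selected_dbs: tuple[str, ...] = SOURCE_DBS
    min_db_occurrence: int = 1
    species: str = "any"
    methods: frozenset[str] | str = "all"
    starbase_min_clip: int = 1

    def validate(self) -> None:
        unknown = set(self.selected_dbs) - set(SOURCE_DBS)
        if unknown:
            raise ConfigError(f"unknown source databases: {sorted(unknown)}")
        if not self.selected_dbs:
            raise ConfigError("at least one source database must be selected")
        if not 1 <= self.min_db_occurrence <= 4:
            raise ConfigError("min_db_occurrence must be in [1, 4]")
        if self.min_db_occurrence > len(self.selected_dbs):
            raise ConfigError(
                "min_db_occurrence exceeds the number of selected databases")
        if self.starbase_min_clip < 1:
            raise ConfigError("starbase_min_clip must be positive")

    def _method_set(self) -> frozenset[str] | None:
        if self.methods == "all":
            return None
        return frozenset(m.strip().lower() for m in self.methods)


def filter_records(
    records: Iterable[MtiRecord], cfg: FilterConfig
) -> list[MtiRecord]:
    """Apply the record-level criteria (database, species, method, clip).

    An empty result is not an error; downstream stages simply produce
    empty outputs.
    """
    wanted_methods = cfg._method_set()
    selected = set(cfg.selected_dbs)
    out = []
    for rec in records:
        if rec.source_db not in selected:
            continue
        if cfg.species != "any" and rec.species != cfg.species:
            continue
        if wanted_methods is not None:
            labels = {m.strip().lower() for m in rec.methods}
            if not labels & wanted_methods:
                continue
        if rec.source_db == "starbase" and rec.clip_support < cfg.starbase_min_clip:
            continue
        out.append(rec)
    return out


def filter_occurrence(
    linked: Iterable[LinkedMti], cfg: FilterConfig
) -> list[LinkedMti]:
    """Keep pairs reported by at least ``min_db_occurrence`` databases."""
    return [mti for mti in linked if mti.popcount() >= cfg.min_db_occurrence]


def filter_by_user_mirnas(
    linked: Iterable[LinkedMti],
    user_ids: Sequence[MirnaIdentifier] | None,
    policy: MatchPolicy,
) -> list[LinkedMti]:
    """Keep pairs whose miRNA key matches any user identifier.

    A missing user list is a no-op (the annotation-only and browse use
    cases).  Matching uses the same wildcard semantics as identifier
    comparison: a shortened user identifier retains every key that agrees
    on its stated components.
    """
    if user_ids is None:
        return list(linked)
    out = []
    for mti in linked:
        ref = parse_mirna_id(mti.mirna_key)
        if any(match(q, ref, policy) for q in user_ids):
            out.append(mti)
    return out


def filter_by_user_targets(
    linked: Iterable[LinkedMti], target_accessions: set[str] | None
) -> list[LinkedMti]:
    """Keep pairs whose accession is in the user's annotation set.

    A missing target file is a no-op (miRNA-list-only and browse use
    cases).
    """
    if target_accessions is None:
        return list(linked)
    return [mti for mti in linked if mti.accession in target_accessions]
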