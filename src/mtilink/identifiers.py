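"""Parsing, normalization and semantic comparison of mature miRNA identifiers.

Mature miRNA names follow the miRBase convention
``<species>-<core>[-<arm>]``, e.g. ``hsa-miR-301b-3p``: a 3-4 letter
organism prefix, a core name, and an optional hairpin-arm suffix
(``-3p``/``-5p``).  Users routinely supply shortened forms (``miR-301b``,
``miR-301b-3p``, ``hsa-miR-301b``); an omitted component acts as a
wildcard when identifiers are compared.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "MirnaIdentifier",
    "MatchPolicy",
    "MirnaParseError",
    "parse_mirna_id",
    "cluster_key",
    "match",
    "read_mirna_list",
]

#: Core-name stems recognized by the parser.  A leading 3-4 letter token is
#: consumed as a species prefix only when the remainder starts with one of
#: these, which keeps "let-7a" from parsing as prefix "let" + core "7a".
CORE_STEMS = ("mir", "let", "lin", "bantam")

_PREFIX_RE = re.compile(r"^([A-Za-z]{3,4})-(.+)$", re.DOTALL)


class MirnaParseError(ValueError):
    """Raised for strings that cannot be interpreted as a miRNA identifier."""


def _has_core_stem(s: str) -> bool:
    low = s.lower()
    return any(low.startswith(stem) for stem in CORE_STEMS)


@dataclass(frozen=True)
class MirnaIdentifier:
    """A parsed mature miRNA identifier.

    Attributes
    ----------
    raw:
        The string as supplied, untouched.
    species_prefix:
        Lowercased 3-4 letter organism code, or ``None`` when omitted.
    core:
        The core name, e.g. ``miR-301b`` or ``let-7a``; original case kept.
    arm:
        ``"3p"``, ``"5p"`` or ``None``.
    """

    raw: str
    species_prefix: str | None
    core: str
    arm: str | None

    def canonical(self) -> str:
        """Hyphen-joined canonical serialization; parsing it is idempotent."""
        parts = []
        if self.species_prefix:
            parts.append(self.species_prefix)
        parts.append(self.core)
        if self.arm:
            parts.append(self.arm)
        return "-".join(parts)


@dataclass(frozen=True)
class MatchPolicy:
    """Stringency of identifier comparison.

    With all flags off, matching is exact string equality on the canonical
    form.  ``cluster_arms`` treats -3p/-5p variants and arm-less names as
    one cluster; ``ignore_species_prefix`` drops the organism code;
    ``case_insensitive_core`` folds core case (source databases mix
    "miR-1" / "mir-1" capitalization, so it defaults to on).
    """

    ignore_species_prefix: bool = False
    cluster_arms: bool = False
    case_insensitive_core: bool = True

    @classmethod
    def strict(cls) -> "MatchPolicy":
        return cls(False, False, False)

    @classmethod
    def clustered(cls) -> "MatchPolicy":
        """Prefix-agnostic, arm-clustered, case-folded comparison."""
        return cls(True, True, True)


def parse_mirna_id(raw: str) -> MirnaIdentifier:
    """Parse a full or shortened miRNA identifier.

    A species prefix is recognized only as a leading 3-4 letter alphabetic
    token followed by a hyphen whose remainder is itself a valid core.
    An arm is recognized only as a literal trailing ``-3p``/``-5p``
    (case-insensitive).  Trailing copy-number suffixes such as the "-1" of
    miR-302a-1 stay part of the core.

    Raises
    ------
    MirnaParseError
        If the trimmed string is empty or its core does not start with a
        known stem (miR / let / lin / bantam).
    """
    s = raw.strip()
    if not s:
        raise MirnaParseError("empty identifier")

    arm: str | None = None
    low = s.lower()
    if low.endswith("-3p") or low.endswith("-5p"):
        arm = low[-2:]
        s = s[:-3]

    prefix: str | None = None
    m = _PREFIX_RE.match(s)
    if m and _has_core_stem(m.group(2)) and not _has_core_stem(m.group(1)):
        prefix = m.group(1).lower()
        s = m.group(2)

    if not s or not _has_core_stem(s):
        raise MirnaParseError(f"unrecognized miRNA core in {raw!r}")

    return MirnaIdentifier(raw=raw, species_prefix=prefix, core=s, arm=arm)


def cluster_key(ident: MirnaIdentifier, policy: MatchPolicy) -> str:
    """Deterministic grouping key for an identifier under a policy.

    Strips the components the policy ignores: with ``cluster_arms`` the arm
    is dropped, with ``ignore_species_prefix`` the prefix is dropped, and
    the core is lowercased when the policy folds case.
    """
    parts = []
    if ident.species_prefix and not policy.ignore_species_prefix:
        parts.append(ident.species_prefix)
    core = ident.core.lower() if policy.case_insensitive_core else ident.core
    parts.append(core)
    if ident.arm and not policy.cluster_arms:
        parts.append(ident.arm)
    return "-".join(parts)


def match(query: MirnaIdentifier, reference: MirnaIdentifier,
          policy: MatchPolicy = MatchPolicy()) -> bool:
    """Semantic comparison of two identifiers.

    True iff the cores agree (per case policy) and each optional component
    either agrees, is ignored by the policy, or is omitted on at least one
    side — a shortened identifier wildcards its omitted parts, on both the
    query and the reference side.
    """
    cq = query.core.lower() if policy.case_insensitive_core else query.core
    cr = reference.core.lower() if policy.case_insensitive_core else reference.core
    if cq != cr:
        return False
    if (not policy.ignore_species_prefix
            and query.species_prefix and reference.species_prefix
            and query.species_prefix != reference.species_prefix):
        return False
    if (not policy.cluster_arms
            and query.arm and reference.arm
            and query.arm != reference.arm):
        return False
    return True


def read_mirna_list(
    path: str | Path,
) -> tuple[list[MirnaIdentifier], list[tuple[int, str, str]]]:
    """Read a plain-text miRNA list, one identifier per line.

    Lines starting with ``#`` and blank lines are ignored; surrounding
    whitespace is trimmed.  Unparseable lines are not fatal: they are
    collected into a skipped-input report ``(line_no, line, reason)``.
    """
    identifiers: list[MirnaIdentifier] = []
    skipped: list[tuple[int, str, str]] = []
    text = Path(path).read_text(encoding="utf-8")
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            identifiers.append(parse_mirna_id(stripped))
        except MirnaParseError as exc:
            skipped.append((i, stripped, str(exc)))
    return identifiers, skipped


def dedupe_by_key(
    identifiers: Iterable[MirnaIdentifier], policy: MatchPolicy
) -> dict[str, MirnaIdentifier]:
    """Deduplicate identifiers by cluster key, keeping the first seen."""
    out: dict[str, MirnaIdentifier] = {}
    for ident in identifiers:
        out.setdefault(cluster_key(ident, policy), ident)
    return out
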