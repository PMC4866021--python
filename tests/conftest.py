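"""Shared fixtures and the independent brute-force enrichment oracle."""

from __future__ import annotations

import numpy as np
import pytest

from mtilink import FixtureSpec, UniprotEntry, UniprotTable, generate_reference


def brute_force_es(values, hit_mask, weight_p):
    """Reference running-sum enrichment score, coded independently.

    Pure-Python sequential walk: hits add |value|^p / N_R, misses
    subtract 1/(N - N_H); returns (es, 1-based position of the first
    extremum, full running sum).  Kept deliberately naive so it cannot
    share bugs with the vectorized implementation it checks.
    """
    n = len(values)
    n_h = sum(1 for h in hit_mask if h)
    assert 0 < n_h < n
    n_r = sum(abs(v) ** weight_p for v, h in zip(values, hit_mask) if h)
    s = 0.0
    best = 0.0
    best_pos = 0
    run = []
    for i, (v, h) in enumerate(zip(values, hit_mask)):
        if h:
            s += abs(v) ** weight_p / n_r
        else:
            s -= 1.0 / (n - n_h)
        run.append(s)
        if abs(s) > abs(best):
            best = s
            best_pos = i + 1
    return best, best_pos, run


@pytest.fixture(scope="session")
def reference_bundle(tmp_path_factory):
    """A generated reference-database bundle plus its truth manifest."""
    out = tmp_path_factory.mktemp("refdb")
    spec = FixtureSpec(
        n_mirnas=30, n_targets=60, n_species=3,
        occurrence_histogram={1: 30, 2: 12, 3: 5, 4: 1},
        fanout_symbols=3, n_unmappable_accessions=5, n_malformed=7,
        duplicate_records_per_db={"mirtarbase": 4}, seed=11,
    )
    manifest = generate_reference(spec, out)
    return out, manifest


@pytest.fixture
def small_uniprot_table():
    """Hand-built mapping table: GENE1 in three species, plus synonyms."""
    return UniprotTable([
        UniprotEntry("P00001", "GENE1", frozenset({"G1SYN"}), "hsa",
                     "Protein one", frozenset({"GO:0000001"}),
                     frozenset({"XR1"})),
        UniprotEntry("P00002", "GENE1", frozenset(), "mmu"),
        UniprotEntry("P00003", "GENE1", frozenset(), "dre"),
        UniprotEntry("P00004", "GENE2", frozenset({"ALT2"}), "hsa"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
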