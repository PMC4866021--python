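# Methods

## Problem and model

Experimentally validated miRNA–target interactions (MTIs) are scattered
over several curated databases that disagree on miRNA naming, target
naming and validation evidence. The pipeline pools four such sources in
a common interchange schema, maps all targets onto UniProt accessions so
the sources become comparable, and treats "how many databases
independently report a pair" as a first-class stringency axis. On top of
the linked pairs it runs a preranked-GSEA-style enrichment of each
miRNA's target set against a user-supplied ranked list.

## miRNA identifier semantics

An identifier is `[<prefix>-]<core>[-<arm>]`: a 3–4 letter organism
prefix, a core name, an optional `-3p`/`-5p` arm. Parsing rules:

- A leading 3–4 letter token is consumed as a species prefix **only**
  when the remainder starts with a known core stem
  (`miR`/`mir`/`let`/`lin`/`bantam`, case-insensitive). This keeps
  `let-7a` from parsing as prefix `let` + core `7a`.
- Only a literal trailing `-3p`/`-5p` is an arm; copy-number suffixes
  (`miR-302a-1`) stay in the core.
- Strings whose core does not start with a known stem are rejected, not
  guessed at; rejected input lines go into a skipped-input report.

Comparison treats omitted components as wildcards **on both sides**: the
query `miR-301b` matches the reference `hsa-miR-301b-3p` and vice versa.
The original tool's behavior for a reference stored without an arm is
not documented anywhere we could find; the symmetric-wildcard rule is
the simplest one that makes matching commutative, and it is what the
property tests pin down. Core comparison folds case by default because
the sources mix `miR-1`/`mir-1` capitalization; a strict policy (all
flags off) reduces matching to string equality on the canonical form.

## Harmonization and occurrence counting

Symbol→UniProt mapping is exact token equality (case-insensitive)
against gene symbol, synonyms and cross-references. No fuzzy matching:
in species-agnostic mode a fuzzy match would silently inflate homology
hits. Database occurrence is counted on (miRNA key, accession) **after**
UniProt mapping — the mapping exists precisely to make the sources
comparable, and counting on raw symbols would undercount cross-database
agreement. The occurrence string's bit order is fixed as (tarbase,
mirtarbase, mirecords, starbase). In agnostic mode occurrence is
counted per accession, so interactions reported for the same symbol in
two organisms reinforce every accession they both map to.

Duplicate records within one source set a bit that is already set;
conservation therefore holds on *distinct* (source, key, accession)
events: Σ popcount(sources) over all pairs equals the number of such
events that survived symbol mapping.

## Filters

All filters are pure subset operations (hence idempotent and commuting):
source-database membership, species (or `any`), validation-method
overlap (labels trimmed and case-folded; any free string accepted),
minimum CLIP-Seq support for starBase records only, and the minimum
database occurrence applied to harmonized pairs. Relaxing
`min_db_occurrence` or `starbase_min_clip` can only grow the result.
An empty result is a warning, not an error.

## Enrichment statistic

For a ranked list of N targets with values r_1 ≥ … ≥ r_N and a set with
N_H members in the list, the running sum starts at 0 and, at rank i,

- adds |r_i|^p / N_R for a member, with N_R = Σ_members |r_i|^p,
- subtracts 1/(N − N_H) for a non-member.

ES is the signed extremum (the first extremal position wins ties); the
increments are normalized so the walk always ends at 0, which every run
asserts to 1e-9. Degenerate sets — no member in the list, all list
entries members, or all hit weights zero — are skipped with a reason
rather than scored. Members absent from the ranked list are dropped
first; the reported set size is the post-intersection N_H.

The weight exponent defaults to p = 1 (weighted) with p = 0 exposed;
rank values may be negative, in which case |value|^p weights the hits.
Ties in rank value keep input order; duplicated accessions keep the
first occurrence with a warning.

**Permutations** resample genes: each of n_perm (default 1000) draws
N_H accessions uniformly without replacement from the list and rescores.
This is set-size-preserving gene resampling, not phenotype permutation.
NES = ES / mean(|permutation ES| with the sign of ES); with no same-sign
permutation NES is reported missing and the set leaves the FDR strata;
ES = 0 gives NES = 0 outright. Permutation ES values are normalized the
same sign-stratified way and pooled over sets; the q-value of a set with
NES\* ≥ 0 is

    q = P(pooled permutation NES ≥ NES*) / P(observed NES ≥ NES*)

clipped to [0, 1], mirrored for negative NES\*, with q = 0 by convention
on an empty permutation stratum. The leading edge takes members at or
before (positive ES) / at or after (negative ES) the extremum.

For the permutation path the extremum is evaluated in closed form at its
only possible locations (at a hit, or immediately before one), which
scores a whole permutation batch as a few vectorized operations; a
dedicated test proves the batch path equal to the O(N) running-sum path
to 1e-12. Per-set permutation seeds are spawned from the run seed in
sorted-key order, so results are independent of set supply order and
bit-identical across reruns with the same seed.

With no ranked list, sets are ranked by descending target count, ties
broken lexicographically by key (the natural secondary key; nothing in
the method constrains it). After an enrichment run the ranking sorts by
descending NES, then ascending q, then descending set size, then key.
`min_set_size` defaults to 3 — small sets produce unstable extrema and
would dominate the ranking by chance.

## Result views

Matrix (accessions × keys, cells = occurrence strings), per-target info
table, set-overlap matrix and the stage-count table are all derived from
the one linked relation and stay pairwise consistent (non-empty cell ⇔
accession in set ⇔ key in info row). The overlap metric is the Jaccard
index — symmetric, size-normalized, standard for set overlap; a raw
intersection count is available as an option. When the enrichment ran,
leading edges replace the full sets in the overlap matrix. Figures
(bar graph, heatmap, per-set enrichment plots) are rendered strictly
from their TSV twins; a rendering failure downgrades to a warning so the
tabular surface is what tests and users rely on.

## Synthetic data

The fixture generator emulates the *record structure* of the four
sources: TarBase-style rows carry a miRBase accession instead of a name
(exercising accession resolution), starBase rows carry CLIP-Seq support
counts, methods come from a small controlled vocabulary, and species /
accession shapes mimic real conventions (`hsa`, `P#####`) without
claiming real identities. Planted structure is exact: an occurrence
histogram (default {1: 30, 2: 12, 3: 5, 4: 1} over 30 miRNAs × 60
targets in 3 species, a small but fully connected testbed), optional
homolog fan-outs, unmappable accessions, malformed rows and duplicate
records, all recorded in a manifest that the pipeline must reproduce
exactly. Ranked-list fixtures plant enriched sets by drawing a chosen
fraction of members from the top quantile of a strictly decreasing,
positive value vector (mimicking a connectivity- or expression-derived
ranking); loading fraction 0 is the null-calibration fixture.

What the fixtures deliberately do **not** emulate: the real databases'
species and method composition, their identifier noise beyond the
planted malformations, true miRNA family structure, and correlated
biological signal in rankings. Passing tests therefore demonstrate the
pipeline's mechanics — parsing, mapping, counting, scoring, calibration
under a uniform null — not recovery rates on any real database release,
which depend entirely on the snapshot used.

## Problem sizes and numerics

Default test and reproduction scales: reference fixtures of ~50–900
planted pairs; enrichment recovery studies use N = 200 ranked targets,
sets of 10, 20 null sets, 1000 permutations, 20 replicates — large
enough for the planted set to separate cleanly (NES well above 1,
q ≈ 0) while the whole suite stays interactive. Floating tolerances:
running-sum termination 1e-9, oracle equivalence 1e-9, batch/trace path
equality 1e-12. All randomness flows from explicit seeds
(`numpy.random.default_rng` / `SeedSequence.spawn`); identical
configuration + seed reproduces every output file byte for byte.

## Known limitations

- Homology mapping rests on shared gene symbols only; genes sharing a
  name across species but diverging in function are not screened out
  (no protein-similarity check).
- No mature↔precursor resolution beyond arm handling, and no validation
  against a live miRBase release.
- Occurrence is a count, not an evidence-quality score; methods are not
  weighted by reliability.
- Only gene-resampling permutations are offered; phenotype permutation
  would need sample-level expression data that the input format does
  not carry.
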