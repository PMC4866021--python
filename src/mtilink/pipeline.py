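"""End-to-end orchestration of the linkage pipeline.

The run dispatches on which inputs are present: with no user files the
filtered reference content is exported (browse mode); a miRNA list
yields per-miRNA target lists; an annotation file of UniProt accessions
yields the miRNAs relevant to those targets; both together link the two;
an additional ranked target list triggers the enrichment analysis.
Every output table is written as TSV; figures are rendered from the same
TSV content and are presentational only — a figure failure downgrades to
a warning.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import linkage
from .enrichment import EnrichmentConfig, EnrichmentOutput, RankedList, run_enrichment
from .filtering import (ConfigError, FilterConfig, filter_by_user_mirnas,
                        filter_by_user_targets, filter_occurrence,
                        filter_records)
from .identifiers import MatchPolicy, dedupe_by_key, read_mirna_list
from .reference import (SOURCE_DBS, harmonize, load_accession_table, load_db,
                        load_uniprot_table, resolve_mirna_ids)

__all__ = ["RunConfig", "RunResult", "run"]


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs.

    ``db_dir`` must contain ``<source>.tsv`` for each selected source
    plus ``mapping.tsv`` and ``accessions.tsv``.  ``ranked_file``
    requires ``target_file`` (enrichment builds on the annotation
    overlap).
    """

    db_dir: Path
    out_dir: Path
    mirna_list: Path | None = None
    target_file: Path | None = None
    ranked_file: Path | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    policy: MatchPolicy = field(default_factory=MatchPolicy)
    agnostic: bool = False
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    overlap_metric: str = "jaccard"
    make_figures: bool = True

    def validate(self) -> None:
        self.filters.validate()
        if self.ranked_file is not None and self.target_file is None:
            raise ConfigError(
                "a ranked file requires an annotation (target) file")
        for db in self.filters.selected_dbs:
            if not (Path(self.db_dir) / f"{db}.tsv").exists():
                raise ConfigError(f"missing reference file {db}.tsv "
                                  f"in {self.db_dir}")
        for name in ("mapping.tsv", "accessions.tsv"):
            if not (Path(self.db_dir) / name).exists():
                raise ConfigError(f"missing {name} in {self.db_dir}")


@dataclass
class RunResult:
    out_dir: Path
    linked: list
    sets: list
    step_counts: pd.DataFrame
    enrichment: EnrichmentOutput | None
    manifest: dict


def _read_target_accessions(path: Path) -> set[str]:
    """First TSV column = UniProt accessions; header row tolerated."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    col = df.columns[0]
    accs = {str(v).strip() for v in df[col] if str(v).strip()}
    if col.lower() not in ("accession", "uniprot", "uniprot_acc", "acc"):
        accs.add(col.strip())  # headerless file: column name is data
    return accs


def run(config: RunConfig) -> RunResult:
    """Execute the pipeline and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    db_dir = Path(config.db_dir)
    acc_table = load_accession_table(db_dir / "accessions.tsv")
    uniprot = load_uniprot_table(db_dir / "mapping.tsv")

    records = []
    load_stats = {}
    n_unresolved = 0
    for db in config.filters.selected_dbs:
        report = load_db(db_dir / f"{db}.tsv", db)
        resolved, dropped = resolve_mirna_ids(report.records, acc_table)
        n_unresolved += dropped
        records.extend(resolved)
        load_stats[db] = {"rows": len(report.records) + report.n_rejected,
                          "rejected": report.n_rejected,
                          "unresolved_accessions": dropped}

    # user miRNA list (optional)
    user_ids = None
    n_raw_lines = None
    n_dedup = None
    skipped_inputs: list = []
    if config.mirna_list is not None:
        ids, skipped_inputs = read_mirna_list(config.mirna_list)
        n_raw_lines = len(ids) + len(skipped_inputs)
        deduped = dedupe_by_key(ids, config.policy)
        n_dedup = len(deduped)
        user_ids = list(deduped.values())
        if skipped_inputs:
            pd.DataFrame(skipped_inputs,
                         columns=["line", "text", "reason"]).to_csv(
                out / "skipped_mirnas.tsv", sep="\t", index=False)

    filtered_records = filter_records(records, config.filters)
    if not filtered_records:
        warnings.warn("no interaction passes the record-level filters")

    harm = harmonize(filtered_records, config.policy, config.agnostic, uniprot)
    linked = filter_by_user_mirnas(harm.linked, user_ids, config.policy)
    if user_ids is not None and not linked:
        warnings.warn("user miRNA list is disjoint from the reference content")
    n_matched_keys = len({m.mirna_key for m in linked})
    n_matched = len(linked)

    linked = filter_occurrence(linked, config.filters)
    n_occ_keys = len({m.mirna_key for m in linked})
    n_occ = len(linked)

    target_accs = None
    if config.target_file is not None:
        target_accs = _read_target_accessions(config.target_file)
    linked = filter_by_user_targets(linked, target_accs)
    n_final_keys = len({m.mirna_key for m in linked})
    n_final = len(linked)

    counts = linkage.step_counts([
        ("input_mirnas", n_raw_lines, sum(s["rows"] - s["rejected"]
                                          for s in load_stats.values())),
        ("parsed_deduplicated", n_dedup, len(filtered_records)),
        ("matched_in_dbs", n_matched_keys, n_matched),
        ("occurrence_filter", n_occ_keys, n_occ),
        ("target_overlap",
         n_final_keys if target_accs is not None else None,
         n_final if target_accs is not None else None),
    ])

    sets = linkage.build_sets(linked)
    matrix = linkage.build_matrix(linked)
    info = linkage.build_info_table(linked, uniprot)

    enr: EnrichmentOutput | None = None
    if config.ranked_file is not None:
        ranked = RankedList.from_file(config.ranked_file)
        enr = run_enrichment(sets, ranked, config.enrichment)
        ranking = enr.ranking
        edges = {k: r.leading_edge for k, r in enr.results.items()}
        overlap = linkage.overlap_heatmap_matrix(
            [s for s in sets if s.mirna_key in edges],
            leading_edges=edges, metric=config.overlap_metric)
    else:
        ranking = linkage.rank_sets_by_size(sets)
        overlap = linkage.overlap_heatmap_matrix(
            sets, metric=config.overlap_metric)

    # tabular outputs — the tested surface
    pd.DataFrame(
        [{"mirna_key": m.mirna_key, "accession": m.accession,
          "species": m.species, "sources": m.sources} for m in linked],
        columns=["mirna_key", "accession", "species", "sources"],
    ).to_csv(out / "mti_table.tsv", sep="\t", index=False)
    matrix.to_csv(out / "matrix.tsv", sep="\t")
    info.to_csv(out / "info.tsv", sep="\t", index=False)
    overlap.to_csv(out / "overlap_matrix.tsv", sep="\t")
    counts.to_csv(out / "step_counts.tsv", sep="\t", index=False)
    ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
    if enr is not None:
        trace_dir = out / "traces"
        trace_dir.mkdir(exist_ok=True)
        for key, trace in enr.traces.items():
            safe = key.replace("/", "_")
            trace.to_csv(trace_dir / f"{safe}.tsv", sep="\t", index=False)
        if enr.skipped:
            pd.DataFrame(enr.skipped,
                         columns=["mirna_key", "reason"]).to_csv(
                out / "skipped_sets.tsv", sep="\t", index=False)

    manifest = {
        "config": _config_dict(config),
        "load_stats": load_stats,
        "n_unresolved_accessions": n_unresolved,
        "n_unmapped_symbols": harm.n_unmapped_symbols,
        "n_unparsed_mirnas": harm.n_unparsed_mirnas,
        "n_skipped_input_mirnas": len(skipped_inputs),
        "step_counts": counts.to_dict(orient="records"),
        "n_linked": n_final,
        "n_sets": len(sets),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))

    if config.make_figures:
        try:
            _render_figures(out, counts, overlap, enr)
        except Exception as exc:  # pragma: no cover - presentational only
            warnings.warn(f"figure rendering failed: {exc}")

    return RunResult(out_dir=out, linked=linked, sets=sets,
                     step_counts=counts, enrichment=enr, manifest=manifest)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in list(d.items()):
        if isinstance(v, Path):
            d[k] = str(v)
    filt = d["filters"]
    if not isinstance(filt["methods"], str):
        filt["methods"] = sorted(filt["methods"])
    filt["selected_dbs"] = list(filt["selected_dbs"])
    return d


def _render_figures(out: Path, counts: pd.DataFrame, overlap: pd.DataFrame,
                    enr: EnrichmentOutput | None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)

    # bar graph of per-stage miRNA / interaction counts
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, col, title in zip(axes, ("n_mirnas", "n_mtis"),
                              ("miRNAs", "interactions")):
        sub = counts[counts[col] != "NA"]
        ax.bar(sub["stage"], sub[col].astype(int))
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(fig_dir / "step_counts.png", dpi=100)
    plt.close(fig)

    if len(overlap) > 0:
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(overlap.to_numpy(dtype=float), vmin=0, cmap="viridis")
        ax.set_xticks(range(len(overlap.columns)))
        ax.set_xticklabels(overlap.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(overlap.index)))
        ax.set_yticklabels(overlap.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="overlap")
        fig.tight_layout()
        fig.savefig(fig_dir / "overlap_heatmap.png", dpi=100)
        plt.close(fig)

    if enr is not None:
        for key, res in enr.results.items():
            fig, ax = plt.subplots(figsize=(6, 3.5))
            ax.plot(range(1, len(res.running_sum) + 1), res.running_sum,
                    color="tab:blue", lw=1, label="running ES")
            for p in res.hit_positions:
                ax.axvline(p + 1, color="black", lw=0.4, ymin=0, ymax=0.08)
            ax.axvline(res.es_position, color="red", lw=1,
                       label=f"ES={res.es:.3f}")
            ax.axhline(0, color="grey", lw=0.5)
            ax.set_xlabel("rank in list")
            ax.set_ylabel("running ES")
            ax.set_title(key)
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(fig_dir / f"enrichment_{key.replace('/', '_')}.png",
                        dpi=100)
            plt.close(fig)
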