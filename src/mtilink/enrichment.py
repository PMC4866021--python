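"""Target-set enrichment analysis over a ranked list (preranked GSEA variant).

Given per-miRNA target sets and a user-supplied list of targets ranked by
some statistic (expression change, network connectivity, ...), each set
is scored by a weighted running sum walked down the ranked list: at a set
member ("hit") at rank i the sum increases by |r_i|^p / N_R with
N_R = Σ_hits |r_i|^p, at a non-member ("miss") it decreases by
1/(N − N_H).  The enrichment score ES is the signed extremum of the sum,
which by construction returns to zero at the end of the list.

Significance is assessed by gene resampling: each permutation draws N_H
accessions uniformly without replacement from the ranked list and
recomputes ES, keeping the set size constant.  The normalized score
NES = ES / mean(|permutation ES| of the same sign), and the FDR q-value
compares the observed NES of a set against the pooled permutation NES
within its sign stratum.  The leading edge is the subset of members at or
before (positive ES) / at or after (negative ES) the extremum — the
members that drive the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .linkage import MtiSet

__all__ = [
    "RankedList",
    "EnrichmentConfig",
    "EnrichmentError",
    "EnrichmentResult",
    "EnrichmentOutput",
    "compute_es",
    "leading_edge",
    "compute_nes",
    "compute_fdr",
    "run_enrichment",
]


class EnrichmentError(ValueError):
    """A set cannot be scored against the ranked list."""


@dataclass
class RankedList:
    """Targets ordered by descending ranking value.

    Ties keep their input order (stable sort); duplicate accessions keep
    the first occurrence, with a warning.  Values may be negative: hit
    weights use |value|^p.
    """

    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.accessions) != len(self.values):
            raise ValueError("accessions and values differ in length")
        if len(self.accessions) < 2:
            raise ValueError("ranked list needs at least 2 entries")
        self._index = {a: i for i, a in enumerate(self.accessions)}

    def __len__(self) -> int:
        return len(self.accessions)

    def positions_of(self, members: Iterable[str]) -> np.ndarray:
        """Sorted 0-based ranks of the members present in the list."""
        pos = sorted(self._index[a] for a in members if a in self._index)
        return np.asarray(pos, dtype=int)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "RankedList":
        accs: list[str] = []
        vals: list[float] = []
        seen: set[str] = set()
        dupes = 0
        for acc, val in pairs:
            if acc in seen:
                dupes += 1
                continue
            seen.add(acc)
            accs.append(acc)
            vals.append(float(val))
        if dupes:
            warnings.warn(f"{dupes} duplicate accessions dropped (first kept)")
        order = np.argsort(-np.asarray(vals), kind="stable")
        return cls([accs[i] for i in order],
                   np.asarray(vals, dtype=float)[order])

    @classmethod
    def from_file(cls, path: str | Path) -> "RankedList":
        """Read a two-column TSV (accession, rank_value), header optional."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        try:  # headerless file: first row is already data
            float(cols[1])
        except ValueError:
            pass
        else:
            df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                             keep_default_na=False)
        acc_col, val_col = df.columns[0], df.columns[1]
        return cls.from_pairs(
            (str(a).strip(), float(v))
            for a, v in zip(df[acc_col], df[val_col]) if str(a).strip()
        )


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the enrichment analysis.

    ``weight_p`` is the running-sum weight exponent (1 = weighted, the
    default; 0 = unweighted Kolmogorov-Smirnov-like).  ``n_perm``
    gene-resampling permutations feed NES and FDR.  Sets smaller than
    ``min_set_size`` after intersection with the ranked list are skipped.
    """

    weight_p: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    min_set_size: int = 3


@dataclass
class EnrichmentResult:
    """Per-set scores and trace."""

    mirna_key: str
    set_size_in_list: int
    es: float
    es_position: int  # 1-based index of the running-sum extremum
    nes: float | None
    fdr_q: float | None
    leading_edge: set[str]
    running_sum: np.ndarray
    hit_positions: np.ndarray  # 0-based ranks of in-list members


def compute_es(
    ranked: RankedList, set_members: Iterable[str], weight_p: float = 1.0
) -> tuple[float, int, np.ndarray]:
    """Weighted running-sum enrichment score of one set.

    Returns ``(es, es_position, running_sum)``: the signed value of the
    maximal absolute deviation from zero, its 1-based position (first
    extremum wins ties), and the full length-N running sum, which ends at
    0 up to floating error.

    Raises :class:`EnrichmentError` when no member is in the list, when
    every list entry is a member (the miss denominator is undefined), or
    when all hit weights are zero.
    """
    pos = ranked.positions_of(set_members)
    n = len(ranked)
    n_h = len(pos)
    if n_h == 0:
        raise EnrichmentError("no set member present in the ranked list")
    if n_h == n:
        raise EnrichmentError("set covers the whole ranked list")
    w = np.abs(ranked.values[pos]) ** weight_p
    n_r = w.sum()
    if n_r == 0:
        raise EnrichmentError("all hit weights are zero")
    inc = np.full(n, -1.0 / (n - n_h))
    inc[pos] = w / n_r
    running = np.cumsum(inc)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx + 1, running


def leading_edge(
    ranked: RankedList,
    set_members: Iterable[str],
    es: float,
    es_position: int,
) -> set[str]:
    """Members that drive the score.

    Positive ES: in-list members at 1-based rank <= ``es_position``;
    negative ES: members at rank >= ``es_position``.
    """
    pos = ranked.positions_of(set_members)
    if es >= 0:
        keep = pos[pos + 1 <= es_position]
    else:
        keep = pos[pos + 1 >= es_position]
    return {ranked.accessions[i] for i in keep}


def _es_batch(values: np.ndarray, positions: np.ndarray,
              weight_p: float) -> np.ndarray:
    """Enrichment scores for a batch of hit-position vectors.

    ``positions`` is (B, N_H), each row sorted ascending.  The running
    sum rises only at hits and falls linearly between them, so its
    extrema occur at a hit (maxima) or immediately before one (minima);
    evaluating the sum at those candidates in closed form scores all B
    permutations without materializing length-N traces.  Ties in |value|
    resolve to the earlier position, matching :func:`compute_es`.
    """
    n = len(values)
    b, n_h = positions.shape
    m = 1.0 / (n - n_h)
    w = np.abs(values[positions]) ** weight_p
    n_r = w.sum(axis=1, keepdims=True)
    safe_r = np.where(n_r == 0, 1.0, n_r)
    c = np.cumsum(w, axis=1) / safe_r
    j = np.arange(n_h)
    miss = (positions - j) * m
    at_hit = c - miss                      # running sum at each hit
    before = np.concatenate(
        [np.zeros((b, 1)), c[:, :-1]], axis=1) - miss  # just before each hit
    # the pre-list value 0 is not a real index; neutralize it
    before[:, 0] = np.where(positions[:, 0] == 0, 0.0, before[:, 0])

    i_max = np.argmax(at_hit, axis=1)
    i_min = np.argmin(before, axis=1)
    rows = np.arange(b)
    best_max = at_hit[rows, i_max]
    best_min = before[rows, i_min]
    pos_max = positions[rows, i_max]
    pos_min = positions[rows, i_min] - 1
    take_max = (np.abs(best_max) > np.abs(best_min)) | (
        (np.abs(best_max) == np.abs(best_min)) & (pos_max <= pos_min))
    return np.where(take_max, best_max, best_min)


def compute_nes(
    ranked: RankedList,
    set_members: Iterable[str],
    es: float,
    n_perm: int,
    rng: np.random.Generator,
    weight_p: float = 1.0,
) -> tuple[float | None, np.ndarray]:
    """Normalized enrichment score via gene-resampling permutations.

    Each permutation draws N_H accessions uniformly without replacement
    from the ranked list (set size held constant) and recomputes ES.
    NES = es / mean(|permutation ES| with the sign of es).  Returns
    ``(nes, perm_es)``; ``nes`` is ``None`` (reported missing) when no
    same-sign permutation exists, and exactly 0 when ``es`` is 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(ranked)
    n_h = len(ranked.positions_of(set_members))
    keys = rng.random((n_perm, n))
    positions = np.sort(np.argsort(keys, axis=1)[:, :n_h], axis=1)
    perm_es = _es_batch(ranked.values, positions, weight_p)
    if es == 0:
        return 0.0, perm_es
    same_sign = perm_es >= 0 if es > 0 else perm_es < 0
    if not same_sign.any():
        return None, perm_es
    return float(es / np.abs(perm_es[same_sign]).mean()), perm_es


def _normalize_perm(perm_es: np.ndarray) -> np.ndarray:
    """Sign-stratified normalization of a permutation ES sample."""
    out = np.empty_like(perm_es, dtype=float)
    pos = perm_es >= 0
    neg = ~pos
    out[pos] = perm_es[pos] / perm_es[pos].mean() if pos.any() else 0.0
    out[neg] = perm_es[neg] / np.abs(perm_es[neg]).mean() if neg.any() else 0.0
    return out


def compute_fdr(
    observed_nes: Mapping[str, float],
    perm_nes_pooled: np.ndarray,
) -> dict[str, float]:
    """FDR q-value per set, sign-stratified over pooled permutation NES.

    For a set with NES* >= 0:
    q = [fraction of non-negative permutation NES >= NES*] /
        [fraction of non-negative observed NES >= NES*], clipped to
    [0, 1]; mirrored for NES* < 0.  A zero denominator (no pooled
    permutation NES in the stratum) gives q = 0 by convention.
    """
    perm = np.asarray(perm_nes_pooled, dtype=float)
    obs = np.asarray(list(observed_nes.values()), dtype=float)
    perm_pos = perm[perm >= 0]
    perm_neg = perm[perm < 0]
    obs_pos = obs[obs >= 0]
    obs_neg = obs[obs < 0]
    q: dict[str, float] = {}
    for key, nes in observed_nes.items():
        if nes >= 0:
            if len(perm_pos) == 0:
                q[key] = 0.0
                continue
            num = (perm_pos >= nes).mean()
            den = (obs_pos >= nes).mean()
        else:
            if len(perm_neg) == 0:
                q[key] = 0.0
                continue
            num = (perm_neg <= nes).mean()
            den = (obs_neg <= nes).mean()
        q[key] = float(min(1.0, num / den)) if den > 0 else 0.0
    return q


@dataclass
class EnrichmentOutput:
    """Full enrichment run: ranking table, per-set traces and results."""

    ranking: pd.DataFrame
    results: dict[str, EnrichmentResult] = field(default_factory=dict)
    traces: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _trace_table(ranked: RankedList, res: EnrichmentResult) -> pd.DataFrame:
    """Per-hit trace: rank index, running ES there, leading-edge flag."""
    rows = []
    for p in res.hit_positions:
        acc = ranked.accessions[p]
        rows.append({
            "accession": acc,
            "rank_index": int(p) + 1,
            "rank_value": float(ranked.values[p]),
            "running_es": float(res.running_sum[p]),
            "leading_edge": acc in res.leading_edge,
        })
    return pd.DataFrame(rows, columns=[
        "accession", "rank_index", "rank_value", "running_es", "leading_edge",
    ])


def run_enrichment(
    sets: Sequence[MtiSet],
    ranked: RankedList,
    config: EnrichmentConfig,
) -> EnrichmentOutput:
    """Score every eligible set against the ranked list.

    Sets whose intersection with the list is smaller than
    ``min_set_size``, or degenerate (empty / whole-list / zero-weight),
    are skipped with a reason.  The ranking table is sorted by descending
    NES, then ascending q, then descending set size, then key; sets with
    missing NES sort last and are excluded from the FDR strata.
    Per-set child seeds are derived from ``config.seed`` in sorted key
    order, so results do not depend on the order sets are supplied in.
    """
    out = EnrichmentOutput(ranking=pd.DataFrame())
    ordered = sorted(sets, key=lambda s: s.mirna_key)
    seeds = np.random.SeedSequence(config.seed).spawn(len(ordered))

    perm_pool: list[np.ndarray] = []
    for s, seed in zip(ordered, seeds):
        n_h = len(ranked.positions_of(s.targets))
        if n_h < config.min_set_size:
            out.skipped.append((s.mirna_key, f"only {n_h} members in ranked list"))
            continue
        if n_h == len(ranked):
            out.skipped.append((s.mirna_key, "set covers the whole ranked list"))
            continue
        try:
            es, es_pos, running = compute_es(ranked, s.targets, config.weight_p)
        except EnrichmentError as exc:
            out.skipped.append((s.mirna_key, str(exc)))
            continue
        rng = np.random.default_rng(seed)
        nes, perm_es = compute_nes(
            ranked, s.targets, es, config.n_perm, rng, config.weight_p)
        if nes is None:
            warnings.warn(f"no same-sign permutation for {s.mirna_key}; "
                          "NES reported missing")
        else:
            perm_pool.append(_normalize_perm(perm_es))
        res = EnrichmentResult(
            mirna_key=s.mirna_key,
            set_size_in_list=n_h,
            es=es,
            es_position=es_pos,
            nes=nes,
            fdr_q=None,
            leading_edge=leading_edge(ranked, s.targets, es, es_pos),
            running_sum=running,
            hit_positions=ranked.positions_of(s.targets),
        )
        out.results[s.mirna_key] = res
        out.traces[s.mirna_key] = _trace_table(ranked, res)

    if out.skipped and not out.results:
        warnings.warn("no eligible set for enrichment analysis")

    with_nes = {k: r.nes for k, r in out.results.items() if r.nes is not None}
    if with_nes:
        pooled = (np.concatenate(perm_pool) if perm_pool
                  else np.empty(0, dtype=float))
        qvals = compute_fdr(with_nes, pooled)
        for key, qv in qvals.items():
            out.results[key].fdr_q = qv

    rows = sorted(
        out.results.values(),
        key=lambda r: (
            r.nes is None,
            -(r.nes if r.nes is not None else 0.0),
            r.fdr_q if r.fdr_q is not None else 1.0,
            -r.set_size_in_list,
            r.mirna_key,
        ),
    )
    out.ranking = pd.DataFrame(
        [{
            "mirna_key": r.mirna_key,
            "set_size": r.set_size_in_list,
            "es": r.es,
            "nes": r.nes if r.nes is not None else "NA",
            "fdr_q": r.fdr_q if r.fdr_q is not None else "NA",
            "leading_edge_size": len(r.leading_edge),
        } for r in rows],
        columns=["mirna_key", "set_size", "es", "nes", "fdr_q",
                 "leading_edge_size"],
    )
    return out
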