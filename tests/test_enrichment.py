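"""Running-sum enrichment score, NES, FDR q-value and leading edge."""

import numpy as np
import pytest

from conftest import brute_force_es
from mtilink import (EnrichmentConfig, RankedList, compute_es, compute_fdr,
                     compute_nes, leading_edge, run_enrichment)
from mtilink.enrichment import EnrichmentError, _es_batch
from mtilink.linkage import MtiSet


def _ranked(n, rng=None, values=None):
    accs = [f"g{i}" for i in range(n)]
    if values is None:
        values = np.sort(rng.exponential(size=n))[::-1] + 0.01
    return RankedList(accs, np.asarray(values, dtype=float))


class TestComputeEs:
    def test_single_top_hit_unweighted(self):
        r = _ranked(4, values=[4, 3, 2, 1])
        es, pos, run = compute_es(r, {"g0"}, weight_p=0)
        assert es == pytest.approx(1.0)
        assert pos == 1
        assert run == pytest.approx([1, 2 / 3, 1 / 3, 0], abs=1e-12)

    def test_single_bottom_hit_unweighted(self):
        r = _ranked(4, values=[4, 3, 2, 1])
        es, pos, run = compute_es(r, {"g3"}, weight_p=0)
        assert es == pytest.approx(-1.0)
        assert pos == 3
        assert run == pytest.approx([-1 / 3, -2 / 3, -1, 0], abs=1e-12)

    def test_weighted_two_hits(self):
        r = _ranked(4, values=[4, 3, 2, 1])
        es, pos, run = compute_es(r, {"g0", "g2"}, weight_p=1)
        assert es == pytest.approx(2 / 3)
        assert pos == 1
        assert run == pytest.approx([2 / 3, 1 / 6, 1 / 2, 0], abs=1e-12)

    def test_degenerate_sets_are_rejected(self):
        r = _ranked(4, values=[4, 3, 2, 1])
        with pytest.raises(EnrichmentError):
            compute_es(r, {"absent"}, 1)
        with pytest.raises(EnrichmentError):
            compute_es(r, {"g0", "g1", "g2", "g3"}, 1)
        zero = RankedList(["g0", "g1", "g2"], [0.0, 0.0, 1.0])
        with pytest.raises(EnrichmentError):
            compute_es(zero, {"g0", "g1"}, weight_p=1)

    def test_members_absent_from_list_are_ignored(self):
        r = _ranked(4, values=[4, 3, 2, 1])
        es_with, _, _ = compute_es(r, {"g0", "nope"}, 0)
        es_without, _, _ = compute_es(r, {"g0"}, 0)
        assert es_with == es_without

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_matches_bruteforce_oracle(self, rng, weight_p):
        for _ in range(200):
            n = int(rng.integers(3, 51))
            r = _ranked(n, rng)
            n_h = int(rng.integers(1, n))
            members = {f"g{i}" for i in rng.choice(n, n_h, replace=False)}
            es, pos, run = compute_es(r, members, weight_p)
            mask = [a in members for a in r.accessions]
            o_es, o_pos, o_run = brute_force_es(r.values, mask, weight_p)
            assert es == pytest.approx(o_es, abs=1e-9)
            assert pos == o_pos
            assert np.max(np.abs(run - np.array(o_run))) < 1e-9

    def test_running_sum_terminates_at_zero(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 80))
            r = _ranked(n, rng)
            n_h = int(rng.integers(1, n))
            members = {f"g{i}" for i in rng.choice(n, n_h, replace=False)}
            _, _, run = compute_es(r, members, 1)
            assert abs(run[-1]) < 1e-9

    def test_reversed_list_negates_unweighted_es(self, rng):
        n = 20
        r = _ranked(n, rng)
        members = {f"g{i}" for i in rng.choice(n, 5, replace=False)}
        es_fwd, _, _ = compute_es(r, members, 0)
        rev = RankedList(list(reversed(r.accessions)), r.values[::-1].copy())
        es_rev, _, _ = compute_es(rev, members, 0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-9)


class TestBatchedPermutationPath:
    """The closed-form batch scorer must equal the running-sum scorer."""

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_equals_compute_es_on_random_draws(self, rng, weight_p):
        n = 60
        r = _ranked(n, rng)
        for n_h in (1, 3, 17, 59):
            draws = np.sort(
                np.stack([rng.choice(n, n_h, replace=False)
                          for _ in range(50)]), axis=1)
            batch = _es_batch(r.values, draws, weight_p)
            for row, es_b in zip(draws, batch):
                members = {f"g{i}" for i in row}
                es, _, _ = compute_es(r, members, weight_p)
                assert es_b == pytest.approx(es, abs=1e-12)


class TestLeadingEdge:
    def test_positive_es_takes_hits_up_to_extremum(self):
        r = _ranked(4, values=[4, 3, 2, 1])
        es, pos, _ = compute_es(r, {"g0", "g2"}, 1)
        assert leading_edge(r, {"g0", "g2"}, es, pos) == {"g0"}

    def test_negative_es_takes_hits_from_extremum_on(self):
        r = _ranked(4, values=[4, 3, 2, 1])
        es, pos, _ = compute_es(r, {"g3"}, 0)
        assert leading_edge(r, {"g3"}, es, pos) == {"g3"}

    def test_all_hits_before_extremum_means_full_set(self, rng):
        r = _ranked(50, rng)
        members = {f"g{i}" for i in range(5)}  # all at the very top
        es, pos, _ = compute_es(r, members, 1)
        assert es > 0
        assert leading_edge(r, members, es, pos) == members


class TestNes:
    def test_zero_es_gives_zero_nes(self, rng):
        r = _ranked(10, rng)
        nes, _ = compute_nes(r, {"g1", "g5"}, 0.0, 50,
                             np.random.default_rng(0))
        assert nes == 0.0

    def test_near_degenerate_set_self_normalizes_to_about_one(self, rng):
        # N_H = N-1 forces every permutation draw to be nearly the
        # observed set, so |NES| ~ es / mean|perm es| ~ 1
        r = _ranked(8, rng)
        members = {f"g{i}" for i in range(7)}
        es, _, _ = compute_es(r, members, 1)
        nes, _ = compute_nes(r, members, es, 500, np.random.default_rng(0))
        assert nes == pytest.approx(np.sign(es), rel=0.35)

    def test_fixed_seed_reproduces_bitwise_and_seeds_differ(self, rng):
        r = _ranked(100, rng)
        members = {f"g{i}" for i in rng.choice(100, 10, replace=False)}
        es, _, _ = compute_es(r, members, 1)
        nes_a, perm_a = compute_nes(r, members, es, 200,
                                    np.random.default_rng(7))
        nes_b, perm_b = compute_nes(r, members, es, 200,
                                    np.random.default_rng(7))
        nes_c, _ = compute_nes(r, members, es, 200,
                               np.random.default_rng(8))
        assert nes_a == nes_b
        assert (perm_a == perm_b).all()
        assert nes_a != nes_c

    def test_top_loaded_set_gets_nes_above_one(self, rng):
        r = _ranked(200, rng)
        members = {f"g{i}" for i in rng.choice(20, 10, replace=False)}
        es, _, _ = compute_es(r, members, 1)
        nes, _ = compute_nes(r, members, es, 500, np.random.default_rng(0))
        assert nes > 1


class TestFdr:
    def test_most_extreme_nes_has_smallest_q_in_stratum(self, rng):
        observed = {f"s{i}": float(v)
                    for i, v in enumerate(rng.normal(size=15))}
        pooled = rng.normal(size=2000)
        q = compute_fdr(observed, pooled)
        pos = {k: v for k, v in observed.items() if v >= 0}
        best = max(pos, key=pos.get)
        assert all(q[best] <= q[k] for k in pos)
        assert all(0 <= v <= 1 for v in q.values())

    def test_observed_beyond_all_permutations_gets_zero(self):
        q = compute_fdr({"s": 5.0}, np.array([0.5, 1.0, -0.3]))
        assert q["s"] == 0.0

    def test_empty_stratum_gives_zero_by_convention(self):
        q = compute_fdr({"s": -2.0}, np.array([0.5, 1.0]))
        assert q["s"] == 0.0


class TestRunEnrichment:
    def _sets_and_ranked(self, rng, planted=True):
        r = _ranked(150, rng)
        sets = []
        if planted:
            sets.append(MtiSet("planted", {f"g{i}" for i in range(8)}))
        for j in range(10):
            members = {f"g{i}" for i in rng.choice(150, 8, replace=False)}
            sets.append(MtiSet(f"null{j}", members))
        return sets, r

    def test_planted_set_ranks_first_by_nes(self, rng):
        sets, r = self._sets_and_ranked(rng)
        out = run_enrichment(sets, r, EnrichmentConfig(n_perm=300, seed=5))
        assert out.ranking.iloc[0]["mirna_key"] == "planted"

    def test_trace_rows_and_leading_edge_flags_consistent(self, rng):
        sets, r = self._sets_and_ranked(rng)
        out = run_enrichment(sets, r, EnrichmentConfig(n_perm=100, seed=5))
        for key, trace in out.traces.items():
            res = out.results[key]
            assert len(trace) == res.set_size_in_list
            flagged = set(trace[trace["leading_edge"]]["accession"])
            assert flagged == res.leading_edge

    def test_small_sets_are_skipped_with_reason(self, rng):
        r = _ranked(50, rng)
        sets = [MtiSet("tiny", {"g0", "g1"}),
                MtiSet("ok", {f"g{i}" for i in range(5)})]
        out = run_enrichment(sets, r, EnrichmentConfig(n_perm=50, seed=1,
                                                       min_set_size=3))
        assert [k for k, _ in out.skipped] == ["tiny"]
        assert list(out.results) == ["ok"]

    def test_result_order_independent_of_input_set_order(self, rng):
        sets, r = self._sets_and_ranked(rng)
        cfg = EnrichmentConfig(n_perm=100, seed=9)
        a = run_enrichment(sets, r, cfg)
        b = run_enrichment(list(reversed(sets)), r, cfg)
        assert a.ranking.equals(b.ranking)


class TestRankedList:
    def test_duplicates_keep_first_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            r = RankedList.from_pairs([("a", 3.0), ("b", 2.0), ("a", 9.0)])
        assert r.accessions == ["a", "b"]
        assert list(r.values) == [3.0, 2.0]

    def test_ties_keep_input_order(self):
        r = RankedList.from_pairs([("a", 1.0), ("b", 2.0), ("c", 1.0)])
        assert r.accessions == ["b", "a", "c"]

    def test_file_round_trip_with_header(self, tmp_path):
        path = tmp_path / "ranked.tsv"
        path.write_text("accession\trank_value\nP1\t3.5\nP2\t-1.0\n")
        r = RankedList.from_file(path)
        assert r.accessions == ["P1", "P2"]
        assert list(r.values) == [3.5, -1.0]
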