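"""Benchmark harness: ranks, spike-in statistics, complementarity."""

import numpy as np
import pytest
from scipy import stats

from phenoprio import benchmark as bm
from phenoprio.errors import RuntimeFailure, UsageError
from phenoprio.synthetic_kg import generate_cases


class TestCausalRank:
    def test_rank_and_output_size(self):
        lst = bm.RankedGeneList(tool="t", case_id="c", genes=(7, 4204, 8085))
        rec = bm.causal_rank(lst, 4204)
        assert rec.rank == 2 and rec.output_size == 3 and not rec.missed

    def test_absent_gene_is_missed(self):
        lst = bm.RankedGeneList(tool="t", case_id="c", genes=(7, 8085))
        rec = bm.causal_rank(lst, 4204)
        assert rec.missed and rec.rank_label() == "MISSED"

    def test_missed_counts_equal_set_difference(self, kg):
        rng = np.random.default_rng(12)
        genes = sorted({a.gene for a in kg.store.gdas})
        n_missed_direct = 0
        records = []
        for i in range(40):
            returned = tuple(
                int(g) for g in rng.choice(genes, size=10, replace=False)
            )
            causal = int(rng.choice(genes))
            lst = bm.RankedGeneList(tool="t", case_id=f"c{i}", genes=returned)
            records.append(bm.causal_rank(lst, causal))
            n_missed_direct += causal not in set(returned)
        assert sum(r.missed for r in records) == n_missed_direct

    def test_duplicate_genes_rejected(self):
        with pytest.raises(UsageError, match="duplicate"):
            bm.RankedGeneList(tool="t", case_id="c", genes=(1, 1))


class TestPanelRank:
    def test_causal_first_independent_of_rng(self):
        panel = set(range(1, 21))
        lst = bm.RankedGeneList(tool="t", case_id="c",
                                genes=(5, 900, 2, 3))  # 900 outside panel
        for seed in range(5):
            assert bm.panel_rank(lst, panel, 5,
                                 np.random.default_rng(seed)) == 1

    def test_fifteen_of_twenty_draws_between_16_and_20(self):
        panel = set(range(1, 21))
        lst = bm.RankedGeneList(tool="t", case_id="c",
                                genes=tuple(range(1, 16)))  # 15 panel genes
        rng = np.random.default_rng(0)
        draws = [bm.panel_rank(lst, panel, 20, rng) for _ in range(200)]
        assert set(draws) <= {16, 17, 18, 19, 20}

    def test_imputed_rank_uniform_over_tail(self):
        # 10^4 draws in the 15-of-20 scenario: goodness of fit to the
        # uniform distribution on {16..20}
        panel = set(range(1, 21))
        lst = bm.RankedGeneList(tool="t", case_id="c",
                                genes=tuple(range(1, 16)))
        rng = np.random.default_rng(1)
        draws = np.array([bm.panel_rank(lst, panel, 20, rng)
                          for _ in range(10_000)])
        counts = np.bincount(draws, minlength=21)[16:21]
        assert counts.sum() == 10_000
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_causal_not_in_panel_fatal(self):
        lst = bm.RankedGeneList(tool="t", case_id="c", genes=())
        with pytest.raises(UsageError, match="not part of the candidate panel"):
            bm.panel_rank(lst, {1, 2, 3}, 99, np.random.default_rng(0))


def _constant_tool(cases, kind="first"):
    """A fake tool that returns the causal gene first, or nothing at all."""
    per_case = {}
    for case in cases:
        genes = tuple(case.causal_genes) if kind == "first" else ()
        per_case[case.case_id] = bm.RankedGeneList(
            tool=kind, case_id=case.case_id, genes=genes
        )
    return {kind: per_case}


@pytest.fixture(scope="module")
def cases_and_pool():
    from phenoprio.synthetic_kg import GeneratorConfig, generate_kg

    kg = generate_kg(GeneratorConfig(seed=21))
    cases = generate_cases(kg, 30, dual_fraction=0.1)
    pool = sorted({a.gene for a in kg.store.gdas})
    return kg, cases, pool


class TestSimulateClinicalExome:

    def test_oracle_tool_every_median_is_one(self, cases_and_pool):
        _kg, cases, pool = cases_and_pool
        results = bm.simulate_clinical_exome(
            _constant_tool(cases, "first"), cases, pool, seed=3
        )
        assert results and all(r.median_rank == 1 for r in results)

    def test_null_tool_ranks_uniform_median_concentrates(self, cases_and_pool):
        _kg, cases, pool = cases_and_pool
        results = bm.simulate_clinical_exome(
            _constant_tool(cases, "null"), cases, pool, seed=3
        )
        ranks = np.concatenate([r.permutation_ranks for r in results])
        assert ranks.min() >= 1 and ranks.max() <= 20
        # median of 25 uniform draws on {1..20} concentrates near 10-11
        medians = [r.median_rank for r in results]
        assert 9 <= np.median(medians) <= 12

    def test_median_is_13th_order_statistic(self, cases_and_pool):
        _kg, cases, pool = cases_and_pool
        results = bm.simulate_clinical_exome(
            _constant_tool(cases, "null"), cases, pool, seed=4
        )
        for r in results:
            assert isinstance(r.median_rank, int)
            assert r.median_rank == sorted(r.permutation_ranks)[12]

    def test_reproducible_and_panels_shared_across_tools(self, cases_and_pool):
        _kg, cases, pool = cases_and_pool
        tools = {**_constant_tool(cases, "first"), **_constant_tool(cases, "null")}
        a = bm.simulate_clinical_exome(tools, cases, pool, seed=7)
        b = bm.simulate_clinical_exome(tools, cases, pool, seed=7)
        assert a == b
        c = bm.simulate_clinical_exome(tools, cases, pool, seed=8)
        assert a != c

    def test_pool_too_small_fatal(self, cases_and_pool):
        _kg, cases, pool = cases_and_pool
        with pytest.raises(RuntimeFailure, match="pool too small"):
            bm.simulate_clinical_exome(
                _constant_tool(cases, "first"), cases, pool[:10], seed=1
            )


class TestCumulativeDetection:
    def test_single_result_step_function(self):
        r = bm.SpikeInResult(tool="t", case_id="c", causal_gene=1,
                             median_rank=3, permutation_ranks=(3,) * 25)
        table = bm.cumulative_detection([r])
        assert list(table["t"]) == [0, 0] + [1] * 18

    def test_equals_histogram_cumsum_and_saturates(self, kg):
        rng = np.random.default_rng(13)
        results = [
            bm.SpikeInResult(tool="t", case_id=f"c{i}", causal_gene=i,
                             median_rank=int(rng.integers(1, 21)),
                             permutation_ranks=(1,) * 25)
            for i in range(60)
        ]
        table = bm.cumulative_detection(results)
        hist = np.bincount([r.median_rank for r in results], minlength=21)[1:]
        assert list(table["t"]) == list(np.cumsum(hist))
        assert table["t"].is_monotonic_increasing
        assert table["t"].iloc[-1] == 60


def _records(tool, hits, all_pairs):
    return [
        bm.CausalRankRecord(tool=tool, case_id=cid, causal_gene=g,
                            rank=1 if (cid, g) in hits else None,
                            output_size=100)
        for cid, g in all_pairs
    ]


class TestUniqueHits:
    def test_single_tool_unique_equals_hits(self):
        pairs = [(f"c{i}", i) for i in range(10)]
        hits = set(pairs[:4])
        s = bm.unique_hits({"a": _records("a", hits, pairs)}, cutoff=20)
        assert s.per_tool_unique == {"a": 4} and s.union_count == 4

    def test_disjoint_tools_add_up(self):
        pairs = [(f"c{i}", i) for i in range(10)]
        s = bm.unique_hits(
            {"a": _records("a", set(pairs[:3]), pairs),
             "b": _records("b", set(pairs[3:7]), pairs)},
            cutoff=20,
        )
        assert s.per_tool_unique == {"a": 3, "b": 4}
        assert s.union_count == 7 and s.unique_total == 7

    def test_matches_set_algebra_oracle_across_cutoffs(self):
        rng = np.random.default_rng(14)
        pairs = [(f"c{i}", 100 + i) for i in range(40)]
        tools = {}
        truth_ranks = {}
        for t in "abcdefgh":
            ranks = {p: int(rng.integers(1, 61)) for p in pairs}
            truth_ranks[t] = ranks
            tools[t] = [
                bm.CausalRankRecord(tool=t, case_id=cid, causal_gene=g,
                                    rank=ranks[(cid, g)], output_size=60)
                for cid, g in pairs
            ]
        for cutoff in (1, 5, 20, 50):
            s = bm.unique_hits(tools, cutoff)
            hit_sets = {
                t: {p for p in pairs if truth_ranks[t][p] <= cutoff}
                for t in tools
            }
            union = set().union(*hit_sets.values())
            assert s.union_count == len(union)
            for t in tools:
                others = set().union(
                    *(hit_sets[o] for o in tools if o != t)
                )
                assert s.per_tool_unique[t] == len(hit_sets[t] - others)
            assert s.unique_total <= s.union_count <= s.total_pairs

    def test_order_invariance(self):
        rng = np.random.default_rng(15)
        pairs = [(f"c{i}", i) for i in range(20)]
        tools = {
            t: _records(t, {p for p in pairs if rng.random() < 0.4}, pairs)
            for t in "abc"
        }
        s1 = bm.unique_hits(tools, 20)
        s2 = bm.unique_hits(dict(reversed(list(tools.items()))), 20)
        assert s1.per_tool_unique == s2.per_tool_unique
        assert s1.union_count == s2.union_count

    def test_mismatched_pair_sets_fatal(self):
        pairs = [(f"c{i}", i) for i in range(5)]
        tools = {"a": _records("a", set(), pairs),
                 "b": _records("b", set(), pairs[:-1])}
        with pytest.raises(RuntimeFailure, match="different"):
            bm.unique_hits(tools, 20)


class TestReaders:
    def test_generic_tsv_round_trip(self, tmp_path):
        p = tmp_path / "tool.tsv"
        p.write_text("case_id\tgenes\nc1\t5,3,8\nc2\t\n", encoding="utf-8")
        out = bm.read_tool_outputs(p, "x")
        assert out["c1"].genes == (5, 3, 8)
        assert out["c2"].genes == ()
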