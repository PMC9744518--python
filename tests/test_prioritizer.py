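"""Core ranking pipeline: mapping, retrieval, ordering, output format."""

import numpy as np
import pytest

from phenoprio.knowledge_store import (
    Concept,
    GeneDiseaseAssociation,
    KnowledgeStore,
    load_store,
)
from phenoprio.prioritizer import (
    map_hpo_to_cuis,
    prioritize,
    retrieve_gdas,
    write_output,
)
from phenoprio.benchmark import read_genes_only

from oracles import matched_cuis_oracle, rank_oracle, read_tables


def small_store():
    return KnowledgeStore(
        concepts=[Concept("C0000001"), Concept("C0000002"),
                  Concept("C0000003")],
        gdas=[
            GeneDiseaseAssociation(gene=10, cui="C0000001", score=0.3),
            GeneDiseaseAssociation(gene=10, cui="C0000002", score=0.9,
                                   pmids=frozenset({5})),
            GeneDiseaseAssociation(gene=20, cui="C0000001", score=0.5),
        ],
        metathesaurus=[("HP:0000001", "C0000001"), ("HP:0000001", "C0000002")],
        hoom=[("HP:0000001", "Orphanet:1", "C0000002")],
        pda=[("HP:0000001", "C0000002"), ("HP:0000001", "C0000003"),
             ("HP:0000002", "C0000003")],
    )


class TestMapping:
    def test_single_path_term(self):
        store = small_store()
        assert map_hpo_to_cuis(store, {"HP:0000002"}) == {"C0000003"}

    def test_three_path_union(self):
        store = small_store()
        assert map_hpo_to_cuis(store, {"HP:0000001"}) == {
            "C0000001", "C0000002", "C0000003"
        }

    def test_unmapped_term_contributes_nothing(self):
        store = small_store()
        assert map_hpo_to_cuis(store, {"HP:0000001", "HP:0009999"}) == \
            map_hpo_to_cuis(store, {"HP:0000001"})

    def test_random_subsets_match_table_scan(self, kg):
        tables = read_tables(kg.paths["tabular"])
        rng = np.random.default_rng(3)
        hpos = sorted(kg.ontology.terms)
        for _ in range(50):
            terms = set(rng.choice(hpos, size=int(rng.integers(1, 6)),
                                   replace=False))
            assert map_hpo_to_cuis(kg.store, terms) == \
                matched_cuis_oracle(tables, terms)


class TestRetrieve:
    def test_empty_cuis(self):
        assert retrieve_gdas(small_store(), set()) == []

    def test_index_matches_linear_scan(self, kg):
        rng = np.random.default_rng(4)
        cuis = sorted(kg.store.concepts)
        for _ in range(20):
            subset = set(rng.choice(cuis, size=int(rng.integers(1, 10)),
                                    replace=False))
            got = retrieve_gdas(kg.store, subset)
            expected = [a for a in kg.store.gdas if a.cui in subset]
            assert sorted(got, key=lambda a: (a.cui, a.gene)) == \
                sorted(expected, key=lambda a: (a.cui, a.gene))


class TestPrioritize:
    def test_highest_score_wins(self):
        res = prioritize(small_store(), {"HP:0000001"})
        assert [(g.gene, g.highest_score) for g in res.genes] == [
            (10, 0.9), (20, 0.5)
        ]
        top = res.genes[0]
        assert [e.cui for e in top.evidence] == ["C0000002", "C0000001"]

    def test_ties_break_by_ascending_gene_id(self):
        store = KnowledgeStore(
            concepts=[Concept("C0000001")],
            gdas=[GeneDiseaseAssociation(gene=30, cui="C0000001", score=0.8),
                  GeneDiseaseAssociation(gene=7, cui="C0000001", score=0.8)],
            pda=[("HP:0000001", "C0000001")],
        )
        res = prioritize(store, {"HP:0000001"})
        assert res.gene_ids() == [7, 30]

    def test_no_match_yields_empty_result(self):
        res = prioritize(small_store(), {"HP:0009999"})
        assert res.genes == ()

    def test_adding_terms_is_monotone(self, kg):
        rng = np.random.default_rng(5)
        hpos = sorted(kg.ontology.terms)
        for _ in range(30):
            base = set(rng.choice(hpos, size=2, replace=False))
            extra = base | {hpos[int(rng.integers(len(hpos)))]}
            before = {g.gene: g.highest_score
                      for g in prioritize(kg.store, base).genes}
            after = {g.gene: g.highest_score
                     for g in prioritize(kg.store, extra).genes}
            for gene, score in before.items():
                assert after[gene] >= score

    def test_random_queries_match_brute_force(self, kg):
        tables = read_tables(kg.paths["tabular"])
        rng = np.random.default_rng(6)
        hpos = sorted(kg.ontology.terms)
        for _ in range(100):
            terms = set(rng.choice(hpos, size=int(rng.integers(1, 6)),
                                   replace=False))
            res = prioritize(kg.store, terms)
            assert [(g.gene, g.highest_score) for g in res.genes] == \
                rank_oracle(tables, terms)


class TestWriteOutput:
    def test_golden_row_with_pmids_sorted(self, tmp_path):
        store = KnowledgeStore(
            concepts=[Concept("C0410538")],
            gdas=[GeneDiseaseAssociation(gene=4204, cui="C0410538", score=0.82,
                                         pmids=frozenset({222, 111}))],
            pda=[("HP:0002996", "C0410538")],
        )
        res = prioritize(store, {"HP:0002996"})
        out = tmp_path / "out.tsv"
        write_output(res, out)
        lines = out.read_text(encoding="utf-8").splitlines()
        assert lines[0] == ("gene (NCBI)\thighest GDA score\t"
                            "diseases (UMLS) with sources per disease")
        assert lines[1] == "4204\t0.82\tC0410538 (0.82): 111,222"

    def test_multiple_evidence_pipe_joined(self, tmp_path):
        res = prioritize(small_store(), {"HP:0000001"})
        out = tmp_path / "out.tsv"
        write_output(res, out)
        row = out.read_text(encoding="utf-8").splitlines()[1]
        assert row == "10\t0.9\tC0000002 (0.9): 5|C0000001 (0.3)"

    def test_genes_only_round_trips_through_benchmark_reader(self, kg, tmp_path):
        hpos = sorted(kg.ontology.terms)
        res = prioritize(kg.store, set(hpos[:4]))
        assert res.genes  # fixture query must be non-trivial
        out = tmp_path / "genes.txt"
        write_output(res, out, genes_only=True)
        back = read_genes_only(out, tool="t", case_id="c")
        assert list(back.genes) == res.gene_ids()

    def test_empty_genes_only_is_empty_file(self, tmp_path):
        res = prioritize(small_store(), {"HP:0009999"})
        out = tmp_path / "genes.txt"
        write_output(res, out, genes_only=True)
        assert out.read_bytes() == b""

    def test_repeated_runs_byte_identical(self, kg, tmp_path):
        hpos = sorted(kg.ontology.terms)
        blobs = set()
        for i in range(3):
            res = prioritize(load_store(kg.paths["tabular"],
                                        dialect="tabular"),
                             set(hpos[:5]))
            out = tmp_path / f"run{i}.tsv"
            write_output(res, out)
            blobs.add(out.read_bytes())
        assert len(blobs) == 1
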