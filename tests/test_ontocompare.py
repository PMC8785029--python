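"""Synonym-overlap matching, implicit similarity, and document-set overlap."""

from itertools import combinations

import numpy as np
import pytest

from epilit.fixtures import gen_term_sources
from epilit.ontocompare import (concept_overlap, docset_overlap,
                                export_mapping, synonym_overlap)
from epilit.termsource import Concept, TermSource, normalize


def _source(sid, concepts):
    return TermSource(sid, [
        Concept(f"{sid}{i}", label, frozenset(syns))
        for i, (label, syns) in enumerate(concepts)])


def test_explicit_and_implicit_similarity():
    # b1{s1,s2}, b2{s1}, b3{s2}: explicit edges b1-b2 and b1-b3, and an
    # implicit similarity b2~b3 through the shared neighbour
    src_a = _source("A", [("b1", {"s1", "s2"})])
    src_b = _source("B", [("b2", {"s1"}), ("b3", {"s2"})])
    graph, report = concept_overlap([src_a, src_b])
    edges = {frozenset(e) for e in graph.edges}
    assert edges == {frozenset({("A", "A0"), ("B", "B0")}),
                     frozenset({("A", "A0"), ("B", "B1")})}
    components = graph.components()
    assert len(components) == 1 and len(components[0]) == 3


def test_identical_sources_fully_shared():
    concepts = [("term one", {"syn a"}), ("term two", set())]
    graph, report = concept_overlap([_source("X", concepts),
                                     _source("Y", concepts)])
    assert report["per_source"]["X"]["shared_pct"] == 100.0
    assert report["per_source"]["Y"]["shared_pct"] == 100.0
    for comp in graph.components():
        assert {sid for sid, _ in comp} == {"X", "Y"}


def test_disjoint_sources_share_nothing():
    graph, report = concept_overlap([
        _source("X", [("alpha", {"a"})]), _source("Y", [("beta", {"b"})])])
    assert report["shared_total"] == 0
    syn = synonym_overlap([
        _source("X", [("alpha", {"a"})]), _source("Y", [("beta", {"b"})])])
    assert syn["shared_forms"] == 0
    assert all(v == 0 for v in syn["pairwise_shared_forms"].values())


def test_planted_overlap_fraction_reproduced():
    # 60 shared of 137 concepts: the shared percentage is 43.796
    sources, truth = gen_term_sources(2, 137, 60 / 137, seed=1)
    _, report = concept_overlap(sources)
    assert report["per_source"]["onto0"]["shared"] == 60
    assert report["per_source"]["onto0"]["shared_pct"] == pytest.approx(43.796,
                                                                        abs=5e-4)


def test_requires_two_sources():
    with pytest.raises(ValueError):
        concept_overlap([_source("X", [("a", set())])])
    with pytest.raises(ValueError):
        synonym_overlap([_source("X", [("a", set())])])


def test_synonym_pooled_totals_and_sharing():
    shared = {"overlapping synonym"}
    srcs = [
        _source("P", [("p0", shared | {"p unique"})]),
        _source("Q", [("q0", shared), ("q1", {"q unique"})]),
    ]
    rep = synonym_overlap(srcs)
    assert rep["pooled_total"] == 4
    assert rep["unique_forms"] == 3
    assert rep["shared_forms"] == 1
    assert rep["single_source_forms"] == 2
    assert rep["per_source"]["P"]["shared"] == 1
    assert rep["per_source"]["P"]["total"] == 2
    assert rep["pairwise_shared_forms"][("P", "Q")] == 1


def test_conservation_shared_plus_unshared():
    sources, _ = gen_term_sources(3, 24, 0.25, seed=4)
    _, creport = concept_overlap(sources)
    sreport = synonym_overlap(sources)
    for rep in (creport, sreport):
        for sid, row in rep["per_source"].items():
            assert row["shared"] + row["unshared"] == row["total"]


def test_source_order_invariance():
    sources, _ = gen_term_sources(3, 15, 0.4, seed=2)
    _, r1 = concept_overlap(sources)
    _, r2 = concept_overlap(sources[::-1])
    assert r1["per_source"] == r2["per_source"]


def _brute_force_shared(sources):
    """All-pairs synonym-intersection oracle."""
    forms = {
        s.source_id: {
            c.id: {normalize(f) for f in c.surface_forms if normalize(f)}
            for c in s.concepts}
        for s in sources
    }
    shared = {s.source_id: set() for s in sources}
    for a, b in combinations(sources, 2):
        for ca, fa in forms[a.source_id].items():
            for cb, fb in forms[b.source_id].items():
                if fa & fb:
                    shared[a.source_id].add(ca)
                    shared[b.source_id].add(cb)
    return {sid: len(c) for sid, c in shared.items()}


def test_matches_all_pairs_brute_force():
    rng = np.random.default_rng(8)
    for trial in range(5):
        sources = []
        for s in range(3):
            concepts = []
            for c in range(rng.integers(5, 40)):
                syns = {f"syn{int(rng.integers(0, 30))}"
                        for _ in range(rng.integers(0, 4))}
                concepts.append((f"s{s}c{c} label", syns))
            sources.append(_source(f"S{s}", concepts))
        _, report = concept_overlap(sources)
        expected = _brute_force_shared(sources)
        got = {sid: row["shared"] for sid, row in report["per_source"].items()}
        assert got == expected, trial


def test_component_soundness():
    sources, _ = gen_term_sources(3, 12, 0.5, seed=6)
    graph, _ = concept_overlap(sources)
    for comp in graph.components():
        sub = graph.graph.subgraph(comp)
        import networkx as nx
        assert nx.is_connected(sub)
        for a, b in sub.edges:
            assert graph.shared_synonyms(a, b)


def test_export_mapping_rows(tmp_path):
    src_a = _source("A", [("b1", {"s1"})])
    src_b = _source("B", [("b2", {"s1"})])
    graph, _ = concept_overlap([src_a, src_b])
    rows = export_mapping(graph, tmp_path / "map.tsv")
    assert rows == [{"source_a": "A", "concept_a": "A0",
                     "source_b": "B", "concept_b": "B0",
                     "shared_synonyms": ["s1"]}]
    assert (tmp_path / "map.tsv").read_text().count("\n") == 2


def test_docset_venn_and_ratios():
    sets = {"P": {"1", "2", "3"}, "Q": {"2", "3", "4"}}
    rep = docset_overlap(sets, corpus_size=5)
    assert rep["union"] == 4
    assert rep["venn"] == {"P": 1, "P|Q": 2, "Q": 1}
    assert rep["pairwise"]["P&Q"] == 2
    assert rep["shared_ge2"] == 2
    assert rep["shared_ge2_pct"] == 50.0
    assert rep["coverage_pct"] == 80.0


def test_docset_identical_sets():
    rep = docset_overlap({"P": {"1", "2"}, "Q": {"1", "2"}})
    assert rep["venn"] == {"P|Q": 2}
    assert rep["shared_pct"] == {"P": 100.0, "Q": 100.0}


def test_docset_beyond_four_sets_pairwise_only():
    sets = {f"S{i}": {str(i), "x"} for i in range(5)}
    rep = docset_overlap(sets)
    assert "venn" not in rep
    assert len(rep["pairwise"]) == 10
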