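"""Synonym-overlap comparison of term sources and document-set overlap.

Two concepts match when they share at least one surface form (preferred
label or synonym, compared case-insensitively after trimming — no stemming,
which would merge genuinely distinct terms). Matching is *explicit* between
the two concepts that share the form; chains of explicit matches induce
*implicit* similarity, captured as connected components of the match graph.
A concept counts as "shared" when it matches a concept of another source.

The same machinery yields synonym-level overlap (which surface forms are
reused across sources) and document-set overlap (Venn cells of the
per-ontology annotated document sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .termsource import TermSource, normalize

__all__ = [
    "percentage",
    "SimilarityGraph",
    "concept_overlap",
    "synonym_overlap",
    "docset_overlap",
    "export_mapping",
]


def percentage(part: int, whole: int, decimals: int = 2) -> float:
    """Rounded percentage used by every overlap report (0.0 when whole == 0)."""
    return round(100.0 * part / whole, decimals) if whole else 0.0


@dataclass
class SimilarityGraph:
    """Concept match graph: nodes (source_id, concept_id), edges share a form."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[tuple[str, str]]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[tuple[str, str], tuple[str, str]]]:
        return list(self.graph.edges)

    def components(self) -> list[set[tuple[str, str]]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def shared_synonyms(self, a: tuple[str, str], b: tuple[str, str]) -> list[str]:
        return sorted(self.graph.edges[a, b]["shared"])


def _forms_by_concept(source: TermSource) -> dict[str, frozenset[str]]:
    return {
        c.id: frozenset(f for f in map(normalize, c.surface_forms) if f)
        for c in source.concepts
    }


def concept_overlap(sources: Sequence[TermSource], decimals: int = 3
                    ) -> tuple[SimilarityGraph, dict]:
    """Concept-level overlap graph and report for >=2 term sources."""
    if len(sources) < 2:
        raise ValueError("need at least two term sources to compare")
    forms = {s.source_id: _forms_by_concept(s) for s in sources}

    g = nx.Graph()
    # inverted index: normalized form -> [(source, concept)]
    index: dict[str, list[tuple[str, str]]] = {}
    for s in sources:
        for cid, fs in forms[s.source_id].items():
            node = (s.source_id, cid)
            g.add_node(node)
            for f in fs:
                index.setdefault(f, []).append(node)
    for f, nodes in index.items():
        for a, b in combinations(nodes, 2):
            if a == b:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["shared"].add(f)
            else:
                g.add_edge(a, b, shared={f})

    per_source: dict[str, dict] = {}
    for s in sources:
        sid = s.source_id
        total = s.n_concepts
        shared_nodes = set()
        for cid in forms[sid]:
            node = (sid, cid)
            if any(nb[0] != sid for nb in g.neighbors(node)):
                shared_nodes.add(node)
        shared = len(shared_nodes)
        per_source[sid] = {
            "total": total,
            "shared": shared,
            "unshared": total - shared,
            "shared_pct": percentage(shared, total, decimals),
            "unshared_pct": percentage(total - shared, total, decimals),
        }

    pairwise = {}
    for a, b in combinations([s.source_id for s in sources], 2):
        count = len({
            node for node in g.nodes if node[0] == a
            and any(nb[0] == b for nb in g.neighbors(node))
        } | {
            node for node in g.nodes if node[0] == b
            and any(nb[0] == a for nb in g.neighbors(node))
        })
        pairwise[(a, b)] = count

    report = {
        "per_source": per_source,
        "pairwise_matched_concepts": pairwise,
        "pooled_total": sum(s.n_concepts for s in sources),
        "shared_total": sum(v["shared"] for v in per_source.values()),
        "n_components": nx.number_connected_components(g),
    }
    return SimilarityGraph(g), report


def synonym_overlap(sources: Sequence[TermSource], decimals: int = 3) -> dict:
    """Synonym-level overlap: pooled totals, unique forms, cross-source reuse.

    Counting follows the bookkeeping of the source files: per-source totals
    count stored synonym strings (labels excluded); uniqueness and sharing
    are decided on normalized forms.
    """
    if len(sources) < 2:
        raise ValueError("need at least two term sources to compare")
    form_sources: dict[str, set[str]] = {}
    per_source_forms: dict[str, set[str]] = {}
    for s in sources:
        mine = set()
        for c in s.concepts:
            for syn in c.synonyms:
                f = normalize(syn)
                if f:
                    mine.add(f)
                    form_sources.setdefault(f, set()).add(s.source_id)
        per_source_forms[s.source_id] = mine

    shared_forms = {f for f, owners in form_sources.items() if len(owners) >= 2}
    per_source = {}
    for s in sources:
        sid = s.source_id
        total = s.n_synonyms
        shared = sum(
            1 for c in s.concepts for syn in c.synonyms
            if normalize(syn) in shared_forms
        )
        per_source[sid] = {
            "total": total,
            "shared": shared,
            "unshared": total - shared,
            "shared_pct": percentage(shared, total, decimals),
            "unshared_pct": percentage(total - shared, total, decimals),
        }

    pairwise = {
        (a, b): len(per_source_forms[a] & per_source_forms[b])
        for a, b in combinations([s.source_id for s in sources], 2)
    }
    return {
        "per_source": per_source,
        "pooled_total": sum(s.n_synonyms for s in sources),
        "unique_forms": len(form_sources),
        "single_source_forms": len(form_sources) - len(shared_forms),
        "shared_forms": len(shared_forms),
        "pairwise_shared_forms": pairwise,
    }


def docset_overlap(doc_id_sets: Mapping[str, set[str]],
                   corpus_size: int | None = None,
                   decimals: int = 2) -> dict:
    """Venn cells and sharing ratios for named document-id sets.

    For more than four sets only pairwise intersections are reported (Venn
    cells are limited to four, as in the usual quad diagrams).
    """
    names = sorted(doc_id_sets)
    union: set[str] = set().union(*doc_id_sets.values()) if doc_id_sets else set()
    report: dict = {"sets": {n: len(doc_id_sets[n]) for n in names},
                    "union": len(union)}

    if len(names) <= 4:
        cells = {}
        for doc in union:
            key = tuple(n for n in names if doc in doc_id_sets[n])
            cells[key] = cells.get(key, 0) + 1
        report["venn"] = {"|".join(k): v for k, v in sorted(cells.items())}

    report["pairwise"] = {
        f"{a}&{b}": len(doc_id_sets[a] & doc_id_sets[b])
        for a, b in combinations(names, 2)
    }

    shared_with_other = {
        n: sum(1 for doc in doc_id_sets[n]
               if any(doc in doc_id_sets[m] for m in names if m != n))
        for n in names
    }
    report["shared_pct"] = {
        n: percentage(shared_with_other[n], len(doc_id_sets[n]), decimals)
        for n in names
    }
    docs_in_ge2 = sum(
        1 for doc in union
        if sum(doc in doc_id_sets[n] for n in names) >= 2
    )
    report["shared_ge2"] = docs_in_ge2
    report["shared_ge2_pct"] = percentage(docs_in_ge2, len(union), decimals)
    if corpus_size:
        report["corpus_size"] = corpus_size
        report["coverage_pct"] = percentage(len(union), corpus_size, decimals)
    return report


def export_mapping(graph: SimilarityGraph, path: str | Path | None = None
                   ) -> list[dict]:
    """Cross-source concept-to-concept mapping with witnessing synonyms."""
    rows = []
    for (sa, ca), (sb, cb) in sorted(graph.edges):
        if sa == sb:
            continue
        shared = graph.shared_synonyms((sa, ca), (sb, cb))
        rows.append({"source_a": sa, "concept_a": ca,
                     "source_b": sb, "concept_b": cb,
                     "shared_synonyms": shared})
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source_a\tconcept_a\tsource_b\tconcept_b\tshared_synonyms\n")
            for r in rows:
                fh.write(f"{r['source_a']}\t{r['concept_a']}\t{r['source_b']}\t"
                         f"{r['concept_b']}\t{'|'.join(r['shared_synonyms'])}\n")
    return rows
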