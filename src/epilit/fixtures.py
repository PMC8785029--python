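"""Deterministic synthetic fixtures for every pipeline stage.

Real inputs for this kind of study — a multi-million-citation corpus, five
curated ontologies, a drug vocabulary — are large external downloads. These
generators emulate their *structure* at desk scale with planted, exactly
known ground truth:

* synthetic term sources with a controlled fraction of cross-source shared
  concepts (constructed, not sampled, so overlap reports are predictable);
* synthetic citation corpora where each document independently receives
  B-terms per ontology and drug mentions at planted co-occurrence rates,
  with the resulting per-ontology document-frequency tables recorded during
  generation;
* ranked-list / reference-set pairs with matches at chosen positions for
  exercising the enrichment score.

Background text comes from a small closed vocabulary that is checked for
collisions against every planted term, so the NER stage can never produce a
hit the ground truth does not know about. At least 20 % of planted terms are
multi-word to exercise leftmost-longest matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cooccurrence import CooccurrenceTable, RankedDrugList
from .prioritize import ReferenceSet
from .termsource import Concept, TermSource, normalize

__all__ = [
    "CorpusSpec",
    "GroundTruth",
    "gen_term_sources",
    "gen_corpus",
    "gen_reference_set",
]

# closed background vocabulary; deliberately unlike any planted term
_BACKGROUND = (
    "study patients results clinical treatment observed outcome measured "
    "group control baseline therapy response analysis data cohort trial "
    "effect dose weeks improvement significant reported method findings"
).split()


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus."""

    n_docs: int = 500
    n_ontologies: int = 2
    n_bterms: int = 8            # B-terms per synthetic ontology
    n_drugs: int = 10
    p_bterm: float = 0.6         # P(document mentions >=1 B-term of an ontology)
    drug_probs: Sequence[float] | None = None  # P(drug | doc has B-terms)
    p_drug_background: float = 0.05  # P(drug | doc has no B-terms)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drug_probs is None:
            # strictly decreasing planted co-occurrence rates, 0.8 .. 0.05
            self.drug_probs = list(np.linspace(0.8, 0.05, self.n_drugs))
        if len(self.drug_probs) != self.n_drugs:
            raise ValueError("drug_probs must have one entry per drug")
        for p in (self.p_bterm, self.p_drug_background, *self.drug_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, recomputable from the artifacts."""

    tables: dict[str, CooccurrenceTable] = field(default_factory=dict)
    doc_b_sources: dict[str, set[str]] = field(default_factory=dict)
    doc_drugs: dict[str, set[str]] = field(default_factory=dict)
    shared_concepts: dict[tuple[str, str], int] = field(default_factory=dict)


def _bterm_vocab(ontology: int, n_terms: int) -> list[str]:
    """B-term surface forms; >=20 % multi-word, nested pair included."""
    terms = []
    for t in range(n_terms):
        if t % 5 == 3:
            terms.append(f"focal sign{ontology}x{t} episode")  # 3-token term
        elif t % 5 == 4:
            terms.append(f"sign{ontology}x{t} episode")        # 2-token term
        else:
            terms.append(f"sign{ontology}x{t}")
    return terms


def _drug_vocab(n_drugs: int) -> list[str]:
    return [f"drugine{d:02d}" for d in range(n_drugs)]


def gen_term_sources(
    n_sources: int,
    n_concepts: int,
    synonym_overlap_fraction: float,
    seed: int = 0,
) -> tuple[list[TermSource], GroundTruth]:
    """Synthetic ontologies with exact planted cross-source concept overlap.

    For every pair of sources, ``round(fraction * n_concepts)`` concepts are
    given a pair-specific common synonym, so each source's shared-concept
    count (and the pairwise matched counts) are known by construction.
    """
    if not 0.0 <= synonym_overlap_fraction <= 1.0:
        raise ValueError("overlap fraction must be in [0, 1]")
    n_shared = round(synonym_overlap_fraction * n_concepts)
    truth = GroundTruth()

    raw: list[list[Concept]] = []
    for s in range(n_sources):
        concepts = []
        for c in range(n_concepts):
            syns = {f"source{s} concept{c} alt"} if c % 2 == 0 else set()
            concepts.append(Concept(f"S{s}C{c}", f"source{s} term{c}",
                                    frozenset(syns)))
        raw.append(concepts)

    for a in range(n_sources):
        for b in range(a + 1, n_sources):
            truth.shared_concepts[(f"onto{a}", f"onto{b}")] = n_shared
            for c in range(n_shared):
                link = f"bridge {a}and{b} num{c}"
                for side, idx in ((a, c), (b, c)):
                    old = raw[side][idx]
                    raw[side][idx] = Concept(
                        old.id, old.preferred_label,
                        old.synonyms | {link})

    sources = [TermSource(f"onto{s}", raw[s]) for s in range(n_sources)]
    return sources, truth


def gen_corpus(spec: CorpusSpec, out_dir: str | Path | None = None
               ) -> tuple[list[dict], list[TermSource], TermSource, GroundTruth]:
    """Generate a citation corpus with planted co-occurrences.

    Returns (corpus records, B-term sources, drug vocabulary, ground truth);
    the ground-truth tables are tallied during generation and equal what a
    full annotate-and-aggregate pass recovers. With a fixed seed the
    generated JSON Lines are byte-identical across runs.
    """
    rng = np.random.default_rng(spec.seed)
    bvocabs = {f"onto{o}": _bterm_vocab(o, spec.n_bterms)
               for o in range(spec.n_ontologies)}
    drugs = _drug_vocab(spec.n_drugs)
    _check_collisions(bvocabs, drugs)

    sources = [
        TermSource(oid, [Concept(f"{oid}b{i}", term)
                         for i, term in enumerate(vocab)])
        for oid, vocab in bvocabs.items()
    ]
    drug_source = TermSource(
        "drugs", [Concept(f"d{i}", name) for i, name in enumerate(drugs)],
        role="C")

    truth = GroundTruth(tables={
        oid: CooccurrenceTable(oid, n_docs=spec.n_docs) for oid in bvocabs})
    records = []
    for d in range(spec.n_docs):
        doc_id = f"doc{d:05d}"
        present_ontologies = [oid for oid in bvocabs
                              if rng.random() < spec.p_bterm]
        has_b = bool(present_ontologies)
        doc_drugs = [drug for drug, p in zip(drugs, spec.drug_probs)
                     if rng.random() < (p if has_b else spec.p_drug_background)]

        tokens: list[str] = list(rng.choice(_BACKGROUND, size=6))
        for oid in present_ontologies:
            vocab = bvocabs[oid]
            n_mentions = int(rng.integers(1, 3))
            for term in rng.choice(vocab, size=n_mentions):
                tokens.append(str(term))
                tokens.append(str(rng.choice(_BACKGROUND)))
        for drug in doc_drugs:
            tokens.append(drug)
            tokens.append(str(rng.choice(_BACKGROUND)))

        title = " ".join(tokens[:4]).capitalize()
        abstract = " ".join(tokens[4:])
        records.append({"pmid": doc_id, "title": title,
                        "abstractText": abstract})

        truth.doc_b_sources[doc_id] = set(present_ontologies)
        truth.doc_drugs[doc_id] = set(doc_drugs)
        for oid in present_ontologies:
            table = truth.tables[oid]
            table.n_docs_b += 1
            if doc_drugs:
                table.n_docs_bc += 1
            for drug in doc_drugs:
                table.counts[drug] = table.counts.get(drug, 0) + 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "corpus.jsonl", "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return records, sources, drug_source, truth


def _check_collisions(bvocabs: dict[str, list[str]], drugs: list[str]) -> None:
    """Background words must not collide with any planted term's tokens."""
    planted_tokens = {
        tok for vocab in bvocabs.values() for term in vocab
        for tok in normalize(term).split()
    } | {tok for drug in drugs for tok in normalize(drug).split()}
    clash = planted_tokens & set(_BACKGROUND)
    if clash:
        raise ValueError(f"background vocabulary collides with planted terms: "
                         f"{sorted(clash)}")


def gen_reference_set(
    list_length: int,
    match_positions: Sequence[int],
    set_size: int | None = None,
    label: str = "synthetic-reference",
) -> tuple[RankedDrugList, ReferenceSet]:
    """Ranked list plus reference set with matches exactly at given positions.

    ``match_positions`` are 1-based ranks; ``set_size`` (default: number of
    positions) pads the reference set with drugs absent from the list, and
    may exceed the list length to exercise the degenerate tau-clamp path.
    """
    positions = sorted(set(match_positions))
    if positions and (positions[0] < 1 or positions[-1] > list_length):
        raise ValueError("match positions must lie within 1..list_length")
    if set_size is None:
        set_size = len(positions)
    if set_size < len(positions):
        raise ValueError("set_size smaller than the number of match positions")

    drugs = [f"listdrug{i:03d}" for i in range(1, list_length + 1)]
    counts = list(range(list_length, 0, -1))
    ref = {drugs[p - 1] for p in positions}
    ref |= {f"extradrug{j:03d}" for j in range(set_size - len(positions))}
    ranked = RankedDrugList("synthetic", drugs, counts)
    if not ref:
        raise ValueError("reference set would be empty; give positions or set_size")
    return ranked, ReferenceSet(label, frozenset(ref))
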