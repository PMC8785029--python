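"""Term sources and lookup dictionaries.

An ontology (or a drug vocabulary) enters the pipeline as a flat set of
concepts, each carrying a preferred label and synonym strings — class
hierarchy and axioms are deliberately ignored: for literature-based discovery
the ontology is just a controlled vocabulary of surface forms.

Two on-disk dialects are supported:

* OWL (via rdflib): labels from ``rdfs:label`` / ``skos:prefLabel``, synonyms
  from ``skos:altLabel`` and the common exact/related-synonym annotation
  properties used by OBO-style and BioPortal ontologies.
* a tabular dialect: UTF-8 TSV with a header line and three columns
  ``id``, ``label``, ``synonyms`` (pipe-separated, possibly empty).

Compiled dictionaries map a *normalized* surface form (case-folded,
whitespace-collapsed, punctuation-tokenized) to the concepts it denotes;
optionally each form's token-wise snowball stem is added as an extra entry so
that inflectional variants in text still match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .stemming import stem

__all__ = [
    "Concept",
    "TermSource",
    "Dictionary",
    "normalize",
    "normalize_tokens",
    "load_term_source",
    "write_term_source",
    "build_dictionary",
    "write_dictionary",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def normalize_tokens(text: str) -> tuple[str, ...]:
    """Case-fold and split on whitespace/punctuation into alphanumeric tokens."""
    return tuple(_TOKEN_RE.findall(text.casefold()))


def normalize(text: str) -> str:
    """Canonical single-string form of a surface string (idempotent)."""
    return " ".join(normalize_tokens(text))


@dataclass(frozen=True)
class Concept:
    """One ontology concept: identifier, preferred label, synonym strings."""

    id: str
    preferred_label: str
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("concept id must be nonempty")
        label = self.preferred_label.strip()
        if not label:
            raise ValueError(f"concept {self.id}: empty preferred label")
        object.__setattr__(self, "preferred_label", label)
        syns = frozenset(s.strip() for s in self.synonyms if s.strip())
        object.__setattr__(self, "synonyms", syns)

    @property
    def surface_forms(self) -> frozenset[str]:
        """Every matchable string: the preferred label plus all synonyms."""
        return self.synonyms | {self.preferred_label}


@dataclass
class TermSource:
    """A named flat set of concepts (one ontology or the drug vocabulary)."""

    source_id: str
    concepts: list[Concept]
    role: str = "B"  # "B" (intermediate terms) or "C" (drug names)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.concepts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"term source {self.source_id!r}: duplicate concept ids {dupes}"
            )

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_synonyms(self) -> int:
        """Stored synonym strings, preferred labels excluded."""
        return sum(len(c.synonyms) for c in self.concepts)


@dataclass
class Dictionary:
    """Normalized surface form -> {(concept id, original surface form)}.

    ``labels`` maps concept id -> preferred label so annotations can carry
    the canonical concept name. ``stemmed`` records whether stem-expanded
    entries were added (the annotator then also tries stemmed text tokens).
    """

    source_id: str
    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    stemmed: bool = False

    def max_tokens(self) -> int:
        return max((len(form.split()) for form in self.entries), default=0)


# ---------------------------------------------------------------------------
# loading

def load_term_source(path: str | Path, format: str, *,
                     source_id: str | None = None, role: str = "B") -> TermSource:
    """Load a term source from ``path`` in the declared format.

    Raises OSError for unreadable files and ValueError for an empty or
    malformed source.
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem
    if format == "tabular":
        source = _load_tabular(path, source_id, role)
    elif format == "owl":
        source = _load_owl(path, source_id, role)
    else:
        raise ValueError(f"unknown term-source format {format!r}")
    if not source.concepts:
        raise ValueError(f"term source {source_id!r} ({path}): zero concepts")
    return source


def _load_tabular(path: Path, source_id: str, role: str) -> TermSource:
    concepts = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            cid, label = parts[0].strip(), parts[1]
            syn_field = parts[2] if len(parts) > 2 else ""
            syns = frozenset(s for s in (t.strip() for t in syn_field.split("|")) if s)
            concepts.append(Concept(cid, label, syns))
    return TermSource(source_id, concepts, role)


# annotation properties commonly carrying labels / synonyms
_LABEL_PREDICATES = (
    "http://www.w3.org/2000/01/rdf-schema#label",
    "http://www.w3.org/2004/02/skos/core#prefLabel",
)
_SYNONYM_PREDICATES = (
    "http://www.w3.org/2004/02/skos/core#altLabel",
    "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasRelatedSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasSynonym",
    "http://purl.bioontology.org/ontology/SYN#synonym",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#FULL_SYN",
)


def _load_owl(path: Path, source_id: str, role: str) -> TermSource:
    import rdflib
    from rdflib.namespace import OWL, RDF

    graph = rdflib.Graph()
    graph.parse(str(path))
    label_preds = [rdflib.URIRef(p) for p in _LABEL_PREDICATES]
    syn_preds = [rdflib.URIRef(p) for p in _SYNONYM_PREDICATES]

    concepts = []
    for cls in sorted(set(graph.subjects(RDF.type, OWL.Class))):
        if not isinstance(cls, rdflib.URIRef):
            continue  # anonymous class expressions carry no terms
        label = None
        for pred in label_preds:
            for obj in graph.objects(cls, pred):
                label = str(obj).strip()
                if label:
                    break
            if label:
                break
        if not label:
            continue
        syns: set[str] = set()
        for pred in syn_preds:
            for obj in graph.objects(cls, pred):
                s = str(obj).strip()
                if s and s != label:
                    syns.add(s)
        concepts.append(Concept(str(cls), label, frozenset(syns)))
    return TermSource(source_id, concepts, role)


def write_term_source(source: TermSource, path: str | Path) -> None:
    """Write a term source in the tabular dialect (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\tsynonyms\n")
        for c in source.concepts:
            fh.write(f"{c.id}\t{c.preferred_label}\t{'|'.join(sorted(c.synonyms))}\n")


# ---------------------------------------------------------------------------
# dictionary compilation

def stem_tokens(tokens: Iterable[str]) -> tuple[str, ...]:
    return tuple(stem(t) for t in tokens)


def build_dictionary(source: TermSource, stem: bool = False) -> Dictionary:
    """Compile a term source into a normalized lookup dictionary.

    Every label and synonym contributes its normalized form; with
    ``stem=True`` the token-wise stemmed variant is *added* (never replacing
    the exact form, so exact text always still matches). Forms shared by
    several concepts map to all of them.
    """
    d = Dictionary(source_id=source.source_id, stemmed=stem)
    for concept in source.concepts:
        d.labels[concept.id] = concept.preferred_label
        for surface in sorted(concept.surface_forms):
            tokens = normalize_tokens(surface)
            if not tokens:
                continue
            keys = {" ".join(tokens)}
            if stem:
                keys.add(" ".join(stem_tokens(tokens)))
            for key in keys:
                d.entries.setdefault(key, set()).add((concept.id, surface))
    return d


def write_dictionary(d: Dictionary, path: str | Path) -> None:
    """Persist a compiled dictionary as TSV (form, concept id, surface)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("normalized_form\tconcept_id\tsurface\n")
        for form in sorted(d.entries):
            for cid, surface in sorted(d.entries[form]):
                fh.write(f"{form}\t{cid}\t{surface}\n")
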