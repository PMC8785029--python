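"""Dictionary-based named-entity recognition over a citation corpus.

Documents are tokenized into maximal alphanumeric runs; each compiled
dictionary is matched against contiguous token subsequences with a
leftmost-longest rule (so "status epilepticus" beats the embedded "status").
Matches produce stand-off annotations — document id, 0-based character
offset, length, matched text, concept label, source dictionary — stored
separately from the text itself.

Corpus input is JSON Lines in the BioASQ/Medline dialect: one object per
citation with ``pmid``, ``title`` and ``abstractText``; the matched text is
the title and abstract joined by a single space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from .termsource import Dictionary, normalize_tokens, stem_tokens

logger = logging.getLogger(__name__)

__all__ = [
    "DocumentRecord",
    "Annotation",
    "PresenceSummary",
    "tokenize",
    "annotate_document",
    "annotate_corpus",
    "read_corpus",
    "write_annotations",
]


@dataclass(frozen=True)
class DocumentRecord:
    doc_id: str
    text: str
    year: int | None = None

    @classmethod
    def from_bioasq(cls, obj: dict) -> "DocumentRecord":
        doc_id = str(obj.get("pmid", "") or obj.get("doc_id", ""))
        if not doc_id:
            raise ValueError("citation record without pmid/doc_id")
        title = obj.get("title") or ""
        abstract = obj.get("abstractText") or ""
        text = f"{title} {abstract}" if title and abstract else title or abstract
        year = obj.get("year")
        return cls(doc_id, text, int(year) if year is not None else None)


@dataclass(frozen=True)
class Annotation:
    """Stand-off mention: the slice text[offset:offset+length] == matched_text."""

    doc_id: str
    offset: int
    length: int
    matched_text: str
    concept_label: str
    source_id: str


@dataclass
class PresenceSummary:
    """Which sources hit a document, and which drug concepts — presence only."""

    doc_id: str
    b_sources: set[str] = field(default_factory=set)
    drugs: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {"doc_id": self.doc_id,
             "b_sources": sorted(self.b_sources),
             "drugs": sorted(self.drugs)},
            ensure_ascii=False)

    @classmethod
    def from_json(cls, line: str) -> "PresenceSummary":
        obj = json.loads(line)
        return cls(obj["doc_id"], set(obj["b_sources"]), set(obj["drugs"]))


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Case-folded maximal alphanumeric runs with (token, offset, length)."""
    import re
    out = []
    for m in re.finditer(r"[^\W_]+", text, re.UNICODE):
        out.append((m.group().casefold(), m.start(), m.end() - m.start()))
    return out


def annotate_document(
    doc: DocumentRecord,
    dicts: Sequence[Dictionary],
) -> list[Annotation]:
    """Leftmost-longest matching of every dictionary against one document.

    Within one dictionary matches never overlap; across dictionaries they
    may (a drug name can sit inside a B-term span). Annotations are sorted
    by offset, then source.
    """
    tokens = tokenize(doc.text)
    exact = [t[0] for t in tokens]
    annotations: list[Annotation] = []
    stemmed: list[str] | None = None
    for d in dicts:
        need_stem = d.stemmed
        if need_stem and stemmed is None:
            stemmed = list(stem_tokens(exact))
        max_len = d.max_tokens()
        i = 0
        n = len(tokens)
        while i < n:
            hit = None
            for span in range(min(max_len, n - i), 0, -1):
                key = " ".join(exact[i : i + span])
                concepts = d.entries.get(key)
                if concepts is None and need_stem:
                    concepts = d.entries.get(" ".join(stemmed[i : i + span]))
                if concepts:
                    hit = (span, concepts)
                    break
            if hit is None:
                i += 1
                continue
            span, concepts = hit
            start = tokens[i][1]
            end = tokens[i + span - 1][1] + tokens[i + span - 1][2]
            surface = doc.text[start:end]
            for cid in sorted({cid for cid, _ in concepts}):
                annotations.append(
                    Annotation(doc.doc_id, start, end - start, surface,
                               d.labels[cid], d.source_id))
            i += span
    annotations.sort(key=lambda a: (a.offset, a.source_id, a.concept_label))
    return annotations


def summarize(doc_id: str, annotations: Iterable[Annotation],
              drug_source_ids: frozenset[str]) -> PresenceSummary:
    summary = PresenceSummary(doc_id)
    for a in annotations:
        if a.source_id in drug_source_ids:
            summary.drugs.add(a.concept_label)
        else:
            summary.b_sources.add(a.source_id)
    return summary


def read_corpus(path: str | Path) -> Iterator[dict]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                yield json.loads(line)


def annotate_corpus(
    corpus: Iterable[dict | DocumentRecord],
    dicts: Sequence[Dictionary],
    drug_source_ids: frozenset[str],
    annotation_sink: TextIO | None = None,
) -> Iterator[tuple[str, list[Annotation], PresenceSummary]]:
    """Stream a corpus through the annotator, one document at a time.

    Malformed records are skipped with a logged warning; the running skip
    tally is available as the ``.skipped`` attribute of the generator's
    enclosing state via the returned summaries (see ``run_pipeline`` for the
    manifest counts).
    """
    skipped = 0
    for record in corpus:
        try:
            doc = record if isinstance(record, DocumentRecord) \
                else DocumentRecord.from_bioasq(record)
        except (ValueError, TypeError, KeyError) as exc:
            skipped += 1
            logger.warning("skipping malformed corpus record (%s): %s", exc, record)
            continue
        annotations = annotate_document(doc, dicts)
        if annotation_sink is not None:
            write_annotations(annotations, annotation_sink)
        yield doc.doc_id, annotations, summarize(doc.doc_id, annotations,
                                                 drug_source_ids)
    if skipped:
        logger.warning("corpus pass complete: %d malformed record(s) skipped", skipped)


def write_annotations(annotations: Iterable[Annotation], sink: TextIO) -> None:
    for a in annotations:
        sink.write(json.dumps(asdict(a), ensure_ascii=False) + "\n")
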