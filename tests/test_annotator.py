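"""Dictionary NER: tokenization, leftmost-longest matching, stand-off slices."""

import json

import pytest

from epilit.annotator import (DocumentRecord, annotate_corpus,
                              annotate_document, tokenize)
from epilit.fixtures import CorpusSpec, gen_corpus
from epilit.termsource import (Concept, TermSource, build_dictionary,
                               normalize, normalize_tokens, stem_tokens)


def test_tokenize_offsets():
    assert tokenize("Ketamine, 5 mg") == [
        ("ketamine", 0, 8), ("5", 10, 1), ("mg", 12, 2)]
    assert tokenize("") == []


def test_tokenize_idempotent_on_token_surfaces():
    for tok, _, _ in tokenize("Valproic acid; EEG-confirmed seizures."):
        assert tokenize(tok) == [(tok, 0, len(tok))]


def _dict(source, stem=False):
    return build_dictionary(source, stem=stem)


def test_annotate_document_offsets(seizure_source, drug_source):
    doc = DocumentRecord("d", "Ketamine reduced seizure frequency")
    anns = annotate_document(doc, [_dict(drug_source), _dict(seizure_source)])
    spans = {(a.offset, a.length, a.matched_text, a.concept_label) for a in anns}
    assert spans == {(0, 8, "Ketamine", "Ketamine"),
                     (17, 7, "seizure", "Seizure")}


def test_no_hits_gives_empty(seizure_source):
    doc = DocumentRecord("d", "nothing relevant in this text")
    assert annotate_document(doc, [_dict(seizure_source)]) == []


def test_leftmost_longest_wins(seizure_source):
    # dictionary holds both "status epilepticus" and "status"
    doc = DocumentRecord("d", "status epilepticus persisted")
    anns = annotate_document(doc, [_dict(seizure_source)])
    assert len(anns) == 1
    assert (anns[0].offset, anns[0].length) == (0, 18)
    assert anns[0].matched_text == "status epilepticus"
    assert anns[0].concept_label == "Status epilepticus"


def test_slice_identity_and_no_overlap_within_dict(seizure_source, drug_source):
    doc = DocumentRecord(
        "d", "Status epilepticus treated with ketamine; status improved, "
             "fits and convulsion ceased after Valproic ACID.")
    dicts = [_dict(seizure_source, stem=True), _dict(drug_source, stem=True)]
    anns = annotate_document(doc, dicts)
    assert anns
    for a in anns:
        assert doc.text[a.offset:a.offset + a.length] == a.matched_text
    for d in dicts:
        mine = sorted((a.offset, a.offset + a.length) for a in anns
                      if a.source_id == d.source_id)
        for (s1, e1), (s2, e2) in zip(mine, mine[1:]):
            if (s1, e1) != (s2, e2):
                assert e1 <= s2


def test_stemmed_fallback_matches_inflected_text(seizure_source):
    doc = DocumentRecord("d", "Recurrent seizures were observed")
    assert annotate_document(doc, [_dict(seizure_source, stem=False)]) == []
    anns = annotate_document(doc, [_dict(seizure_source, stem=True)])
    assert [a.concept_label for a in anns] == ["Seizure"]
    assert anns[0].matched_text == "seizures"


def _oracle_annotations(doc, dictionary):
    """Naive oracle: try every dictionary surface form at every token position."""
    toks = tokenize(doc.text)
    exact = [t[0] for t in toks]
    stemmed = list(stem_tokens(exact))
    hits = []
    for form, concepts in dictionary.entries.items():
        ftoks = form.split()
        L = len(ftoks)
        for i in range(len(toks) - L + 1):
            if exact[i:i + L] == ftoks or (
                    dictionary.stemmed and stemmed[i:i + L] == ftoks):
                start = toks[i][1]
                end = toks[i + L - 1][1] + toks[i + L - 1][2]
                for cid, _ in concepts:
                    hits.append((i, L, start, end, cid))
    # leftmost-longest resolution
    hits.sort(key=lambda h: (h[0], -h[1]))
    chosen = set()
    cursor = 0
    for i, L, start, end, cid in hits:
        if i >= cursor:
            chosen.update((s, e - s, c) for hi, hl, s, e, c in hits
                          if (hi, hl) == (i, L))
            cursor = i + L
    return {(s, l, dictionary.labels[c]) for s, l, c in chosen}


def test_oracle_equivalence_on_synthetic_corpus():
    records, sources, drug_source, _ = gen_corpus(CorpusSpec(n_docs=40, seed=11))
    dicts = [build_dictionary(s, stem=True) for s in sources + [drug_source]]
    for rec in records:
        doc = DocumentRecord.from_bioasq(rec)
        anns = annotate_document(doc, dicts)
        for d in dicts:
            got = {(a.offset, a.length, a.concept_label)
                   for a in anns if a.source_id == d.source_id}
            assert got == _oracle_annotations(doc, d), doc.doc_id


def test_malformed_records_skipped(seizure_source, caplog):
    corpus = [{"title": "no pmid"}, {"pmid": "1", "title": "seizure"}]
    out = list(annotate_corpus(corpus, [_dict(seizure_source)], frozenset()))
    assert [doc_id for doc_id, _, _ in out] == ["1"]
    assert any("skipping" in r.message for r in caplog.records)


def test_presence_summary_separates_b_and_drugs(seizure_source, drug_source,
                                                toy_corpus):
    dicts = [_dict(seizure_source, stem=True), _dict(drug_source, stem=True)]
    results = {doc_id: s for doc_id, _, s in
               annotate_corpus(toy_corpus, dicts, frozenset({"drugs"}))}
    assert results["1"].b_sources == {"epitest"}
    assert results["1"].drugs == {"Ketamine"}
    assert results["2"].b_sources == set()
    assert results["2"].drugs == {"Phenobarbital"}
    assert results["3"].drugs == {"Valproic acid", "Phenobarbital"}
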