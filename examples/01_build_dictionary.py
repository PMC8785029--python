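"""Compile an ontology term source into a stemmed NER dictionary.

Builds a tiny epilepsy-flavoured term source in the tabular dialect, loads
it, and compiles lookup dictionaries with and without snowball stemming.
"""

import tempfile
from pathlib import Path

from epilit import build_dictionary, load_term_source

TSV = """id\tlabel\tsynonyms
c1\tSeizure\tfits|convulsion
c2\tStatus epilepticus\tstatus
c3\tAura\t
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "epitest.tsv"
    path.write_text(TSV, encoding="utf-8")
    source = load_term_source(path, "tabular")

print(f"source {source.source_id!r}: {source.n_concepts} concepts, "
      f"{source.n_synonyms} synonyms")

plain = build_dictionary(source, stem=False)
stemmed = build_dictionary(source, stem=True)
print(f"dictionary entries: {len(plain.entries)} exact, "
      f"{len(stemmed.entries)} with stemmed variants")
print("lookup keys for concept c1:",
      sorted(k for k, v in stemmed.entries.items()
             if any(cid == "c1" for cid, _ in v)))
# The stemmed entry ("seizur") lets inflected text ("seizures") match the
# concept while every exact surface form still matches verbatim.
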