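"""Synonym-overlap comparison of term sources, explicit and implicit.

Reproduces the three-concept worked situation: b1 carries synonyms s1 and
s2, b2 carries s1, b3 carries s2 — so b1 matches both explicitly, and b2~b3
are implicitly similar through b1.
"""

from epilit import concept_overlap, synonym_overlap
from epilit.termsource import Concept, TermSource

source_a = TermSource("A", [Concept("b1", "concept b1", frozenset({"s1", "s2"}))])
source_b = TermSource("B", [Concept("b2", "concept b2", frozenset({"s1"})),
                            Concept("b3", "concept b3", frozenset({"s2"}))])

graph, report = concept_overlap([source_a, source_b])
print("explicit matches (edges):")
for (sa, ca), (sb, cb) in graph.edges:
    print(f"  {sa}:{ca} -- {sb}:{cb} via {graph.shared_synonyms((sa, ca), (sb, cb))}")
print("implicit similarity classes (components):", graph.components())
for sid, row in report["per_source"].items():
    print(f"  {sid}: {row['shared']}/{row['total']} concepts shared "
          f"({row['shared_pct']}%)")

syn = synonym_overlap([source_a, source_b])
print(f"synonym forms: {syn['unique_forms']} unique, "
      f"{syn['shared_forms']} used by both sources")
# Every edge is witnessed by at least one identical synonym; connected
# components give the transitive (implicit) similarity classes used for
# cross-ontology concept mapping.
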