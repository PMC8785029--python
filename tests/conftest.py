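import pytest

from epilit.termsource import Concept, TermSource


@pytest.fixture
def seizure_source() -> TermSource:
    """Tiny epilepsy-flavoured B-term source with a nested multi-word term."""
    return TermSource("epitest", [
        Concept("c1", "Seizure", frozenset({"fits", "convulsion"})),
        Concept("c2", "Status epilepticus", frozenset({"status"})),
        Concept("c3", "Aura"),
    ])


@pytest.fixture
def drug_source() -> TermSource:
    return TermSource("drugs", [
        Concept("d1", "Ketamine", frozenset({"ketamine hydrochloride"})),
        Concept("d2", "Phenobarbital"),
        Concept("d3", "Valproic acid"),
    ], role="C")


@pytest.fixture
def toy_corpus() -> list[dict]:
    """Three hand-checkable citations (BioASQ dialect)."""
    return [
        {"pmid": "1", "title": "Ketamine reduced seizure frequency",
         "abstractText": "Status epilepticus resolved after ketamine."},
        {"pmid": "2", "title": "Phenobarbital pharmacokinetics",
         "abstractText": "No mention of the disease here."},
        {"pmid": "3", "title": "Aura preceding convulsion",
         "abstractText": "Valproic acid and phenobarbital were compared."},
    ]
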