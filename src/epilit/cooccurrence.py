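"""Drug / B-term co-occurrence aggregation and document-frequency ranking.

Counting is at document granularity: a drug mentioned ten times in one
citation still contributes one to its count, and a drug's count for an
ontology is the number of documents containing at least one of that
ontology's terms *and* the drug. Ranked lists sort by descending document
frequency with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotator import PresenceSummary

__all__ = [
    "CooccurrenceTable",
    "RankedDrugList",
    "aggregate_counts",
    "rank_drugs",
    "ratio_bc_over_b",
    "write_ranked_list",
    "read_ranked_list",
]


@dataclass
class CooccurrenceTable:
    """Per-ontology document-frequency table.

    counts[drug] = number of documents with >=1 B-term of this ontology and
    that drug; n_docs_b / n_docs_bc tally documents with >=1 B-term, resp.
    >=1 B-term and >=1 drug of any kind.
    """

    ontology_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_docs_b: int = 0
    n_docs_bc: int = 0
    n_docs: int = 0


@dataclass
class RankedDrugList:
    ontology_id: str
    drugs: list[str] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.drugs) != len(self.counts):
            raise ValueError("drugs and counts must align")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError(f"duplicate drugs in ranked list {self.ontology_id!r}")
        if any(a < b for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be non-increasing")

    def __len__(self) -> int:
        return len(self.drugs)


def aggregate_counts(
    summaries: Iterable[PresenceSummary],
    ontology_id: str,
    known_ontologies: frozenset[str] | None = None,
) -> CooccurrenceTable:
    """Tally per-drug co-occurrence document frequencies for one ontology."""
    if known_ontologies is not None and ontology_id not in known_ontologies:
        raise ValueError(f"unknown ontology id {ontology_id!r} "
                         f"(expected one of {sorted(known_ontologies)})")
    table = CooccurrenceTable(ontology_id)
    for s in summaries:
        table.n_docs += 1
        if ontology_id not in s.b_sources:
            continue
        table.n_docs_b += 1
        if s.drugs:
            table.n_docs_bc += 1
        for drug in s.drugs:
            table.counts[drug] = table.counts.get(drug, 0) + 1
    return table


def rank_drugs(table: CooccurrenceTable) -> RankedDrugList:
    """Descending document frequency; ties broken by drug label."""
    ordered = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedDrugList(
        table.ontology_id,
        [d for d, _ in ordered],
        [c for _, c in ordered],
    )


def ratio_bc_over_b(table: CooccurrenceTable, decimals: int = 3) -> float:
    """Percentage of B-term documents that also contain a drug name."""
    if table.n_docs_b == 0:
        raise ValueError(
            f"{table.ontology_id!r}: no documents with B-terms; ratio undefined")
    return round(100.0 * table.n_docs_bc / table.n_docs_b, decimals)


def write_ranked_list(lst: RankedDrugList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdrug\tcount\n")
        for rank, (drug, count) in enumerate(zip(lst.drugs, lst.counts), start=1):
            fh.write(f"{rank}\t{drug}\t{count}\n")


def read_ranked_list(path: str | Path, ontology_id: str | None = None) -> RankedDrugList:
    path = Path(path)
    drugs, counts = [], []
    with open(path, encoding="utf-8") as fh:
        next(fh)  # header
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, drug, count = line.rstrip("\n").split("\t")
            drugs.append(drug)
            counts.append(int(count))
    return RankedDrugList(ontology_id or path.stem, drugs, counts)
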