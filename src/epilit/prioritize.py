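"""ATC filtering and reference-list priority scoring.

Neurological drug repurposing candidates must act on the nervous system, so
ranked lists are filtered to drugs carrying at least one ATC
(Anatomical Therapeutic Chemical) code under a prefix — class ``N`` for the
nervous system, ``N03`` for antiepileptics specifically.

The priority score of a drug in the final combined list is the number of
curated reference drug lists (Lancet, DRUGSE, EFO, U2D) containing it, plus
one if it carries an N03 code: 0 to 5, 5 meaning "recommended everywhere and
approved as an antiepileptic".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cooccurrence import RankedDrugList

logger = logging.getLogger(__name__)

__all__ = [
    "AtcMap",
    "ReferenceSet",
    "PriorityRecord",
    "load_atc_map",
    "load_reference_set",
    "filter_atc",
    "priority_score",
    "build_final_table",
    "write_final_table",
]

_ATC_RE = re.compile(r"^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")


@dataclass
class AtcMap:
    """Drug label -> set of ATC codes (any truncation level, e.g. N, N03AB02)."""

    codes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = {drug.casefold(): set(cs) for drug, cs in self.codes.items()}
        for drug, cs in self.codes.items():
            for code in cs:
                if not _ATC_RE.match(code):
                    raise ValueError(f"{drug}: malformed ATC code {code!r}")

    def lookup(self, drug: str) -> set[str]:
        return self.codes.get(drug.casefold(), set())

    def has_prefix(self, drug: str, prefix: str) -> bool:
        return any(code.startswith(prefix) for code in self.lookup(drug))


@dataclass
class ReferenceSet:
    """A curated plain list of drug names; membership is case-insensitive."""

    label: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        folded = frozenset(i.strip().casefold() for i in self.items if i.strip())
        if not folded:
            raise ValueError(f"reference set {self.label!r} is empty")
        object.__setattr__(self, "items", folded)

    def __contains__(self, drug: str) -> bool:
        return drug.strip().casefold() in self.items

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class PriorityRecord:
    drug: str
    rank: int
    priority: int
    in_lancet: bool
    in_drugse: bool
    in_efo: bool
    in_u2d: bool
    is_n03: bool
    ontology_hits: set[str] = field(default_factory=set)
    relation_type: str | None = None  # free manual annotation, never computed


def load_atc_map(path: str | Path) -> AtcMap:
    """Read a TSV of (drug, comma-separated ATC codes)."""
    codes: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        next(fh)  # header
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            drug, raw = line.rstrip("\n").split("\t")[:2]
            codes.setdefault(drug, set()).update(
                c.strip() for c in raw.split(",") if c.strip())
    return AtcMap(codes)


def load_reference_set(path: str | Path, label: str | None = None) -> ReferenceSet:
    """Read a plain drug list, one name per line, '#' comments allowed."""
    path = Path(path)
    items = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name:
                items.add(name)
    return ReferenceSet(label or path.stem, frozenset(items))


def filter_atc(lst: RankedDrugList, atc: AtcMap, prefix: str = "N") -> RankedDrugList:
    """Keep, in order, drugs with >=1 ATC code under ``prefix``.

    Drugs absent from the ATC map are dropped (real vocabularies are
    incomplete); the drop tally is logged.
    """
    if not prefix:
        raise ValueError("ATC prefix must be nonempty")
    keep_idx = [i for i, d in enumerate(lst.drugs) if atc.has_prefix(d, prefix)]
    unmapped = sum(1 for d in lst.drugs if not atc.lookup(d))
    if unmapped:
        logger.info("%s: %d drug(s) without ATC mapping dropped by filter",
                    lst.ontology_id, unmapped)
    return RankedDrugList(
        lst.ontology_id,
        [lst.drugs[i] for i in keep_idx],
        [lst.counts[i] for i in keep_idx],
    )


def priority_score(drug: str, refsets: Sequence[ReferenceSet], atc: AtcMap) -> int:
    """One point per reference list containing the drug, plus one for ATC N03."""
    score = sum(1 for rs in refsets if drug in rs)
    if atc.has_prefix(drug, "N03"):
        score += 1
    return score


def build_final_table(
    final: RankedDrugList,
    per_ontology: Mapping[str, RankedDrugList],
    refsets: Sequence[ReferenceSet],
    atc: AtcMap,
) -> list[PriorityRecord]:
    """One record per drug of the combined list, in final rank order.

    ``refsets`` order is (Lancet, DRUGSE, EFO, U2D); membership flags follow
    that order.
    """
    if len(refsets) != 4:
        raise ValueError("expected the four reference sets (Lancet, DRUGSE, EFO, U2D)")
    records = []
    for rank, drug in enumerate(final.drugs, start=1):
        flags = [drug in rs for rs in refsets]
        is_n03 = atc.has_prefix(drug, "N03")
        records.append(PriorityRecord(
            drug=drug,
            rank=rank,
            priority=sum(flags) + is_n03,
            in_lancet=flags[0], in_drugse=flags[1],
            in_efo=flags[2], in_u2d=flags[3],
            is_n03=is_n03,
            ontology_hits={oid for oid, lst in per_ontology.items()
                           if drug in lst.drugs},
        ))
    return records


def write_final_table(records: Sequence[PriorityRecord], path: str | Path) -> None:
    cols = ("priority", "rank", "drug", "ontologies",
            "lancet", "drugse", "efo", "u2d", "n03", "type")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                str(r.priority), str(r.rank), r.drug,
                ",".join(sorted(r.ontology_hits)),
                *(("1" if f else "0") for f in
                  (r.in_lancet, r.in_drugse, r.in_efo, r.in_u2d, r.is_n03)),
                r.relation_type or "",
            ]) + "\n")
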