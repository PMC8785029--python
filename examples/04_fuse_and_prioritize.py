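"""Fuse conflicting ranked lists and score the consensus against references.

Three ontology-derived rankings disagree about four drugs; cross-entropy
Monte-Carlo fusion finds the ordering minimizing the mean Spearman footrule
distance, which is then ATC-filtered and priority-scored.
"""

from epilit import (AtcMap, FusionConfig, ReferenceSet, combine_lists,
                    filter_atc, priority_score)
from epilit.cooccurrence import RankedDrugList


def lst(name, drugs):
    return RankedDrugList(name, drugs, list(range(len(drugs), 0, -1)))


lists = [
    lst("epso", ["ketamine", "morphine", "phenobarbital", "diazepam"]),
    lst("esso", ["ketamine", "phenobarbital", "morphine", "diazepam"]),
    lst("epilont", ["phenobarbital", "ketamine", "diazepam", "morphine"]),
]
result = combine_lists(lists, FusionConfig(k=4, method="cemc", seed=7))
print("consensus order:", result.ranking.drugs)
print(f"mean footrule distance to inputs: {result.objective:.3f}")

atc = AtcMap({"ketamine": {"N01AX03"}, "morphine": {"N02AA01"},
              "phenobarbital": {"N03AA02"}, "diazepam": {"N05BA01"}})
nervous = filter_atc(result.ranking, atc, "N")
print("after ATC class-N filter:", nervous.drugs)

refsets = [ReferenceSet(n, frozenset({"phenobarbital", "diazepam"}))
           for n in ("lancet", "drugse", "efo", "u2d")]
for drug in nervous.drugs:
    print(f"  {drug:<14} priority {priority_score(drug, refsets, atc)}")
# Priority 5 = recommended by all four reference lists and classified as an
# antiepileptic (N03); 0 = no external support for epilepsy treatment.
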