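"""Drug Set Enrichment Analysis (DSEA).

A running-sum enrichment score over a ranked drug list D = {d1..dN} against a
reference set R = {r1..rS} of drugs recommended for the disease. Walking down
the list, position i receives an increment

    bonus   ln((S + t)/(S - t))   if d_i is in R   (``corrected`` convention)
    penalty ln((N - t)/(N + t))   otherwise,

where t (tau) is the number of reference drugs seen so far, *including* the
current position. Unlike the classical GSEA statistic, the adaptive tau makes
each successive match worth more and each successive miss cost more, which
keeps the score informative for short lists. The curve's maximum Psi* and its
position k summarize how strongly, and how early, the list is enriched.

Two sign conventions are exposed. ``corrected`` (default) makes matches
positive bonuses and misses non-positive penalties, producing the
rising-then-falling curves the method is meant to yield. ``verbatim`` keeps
the bonus fraction as (S - t)/(S + t), i.e. a negative "bonus"; it is
retained so both readings of the defining formula can be computed and
compared. In both conventions tau is clamped to S - 1 inside the bonus term
only, so the score stays finite once every reference drug has been found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .cooccurrence import RankedDrugList
from .prioritize import ReferenceSet

__all__ = ["EnrichmentCurve", "dsea_curve", "dsea_max", "dsea_profile"]

_CONVENTIONS = ("corrected", "verbatim")


@dataclass
class EnrichmentCurve:
    """Running scores x0..xN (x0 = 0), increments, cumulative match counts."""

    scores: list[float]        # length N+1, scores[0] == 0.0
    increments: list[float]    # length N
    tau: list[int]             # length N, cumulative matches incl. position i
    is_match: list[bool]       # length N
    max_score: float
    max_position: int          # 1-based, smallest index attaining the max
    convention: str

    @property
    def n(self) -> int:
        return len(self.increments)


def _increment(is_match: bool, tau: int, n: int, s: int, convention: str) -> float:
    if is_match:
        if s == 1:
            # single-item reference set: tau clamps to 0, bonus fraction is 1
            return 0.0
        t = min(tau, s - 1)
        ratio = (s + t) / (s - t)
        return math.log(ratio if convention == "corrected" else 1.0 / ratio)
    if n == tau:  # unreachable for a miss (tau < i <= n); guard for safety
        return 0.0
    return math.log((n - tau) / (n + tau))


def dsea_curve(
    D: RankedDrugList | Sequence[str],
    R: ReferenceSet,
    convention: str = "corrected",
) -> EnrichmentCurve:
    """Evaluate the DSEA running sum of ranked list ``D`` against ``R``.

    Membership is tested case-insensitively on drug labels. Raises
    ValueError for an empty list, an empty reference set, or an unknown
    convention.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    drugs = list(D.drugs) if isinstance(D, RankedDrugList) else list(D)
    if not drugs:
        raise ValueError("ranked list is empty")
    s = len(R)
    if s == 0:
        raise ValueError("reference set is empty")
    n = len(drugs)

    scores = [0.0]
    increments: list[float] = []
    taus: list[int] = []
    matches: list[bool] = []
    tau = 0
    for drug in drugs:
        hit = drug in R
        if hit:
            tau += 1
        inc = _increment(hit, tau, n, s, convention)
        increments.append(inc)
        taus.append(tau)
        matches.append(hit)
        scores.append(scores[-1] + inc)

    max_score = max(scores[1:])
    max_position = scores[1:].index(max_score) + 1
    return EnrichmentCurve(scores, increments, taus, matches,
                           max_score, max_position, convention)


def dsea_max(curve: EnrichmentCurve) -> tuple[float, int]:
    """Maximum of x1..xN and the smallest 1-based index attaining it."""
    return curve.max_score, curve.max_position


def dsea_profile(
    lists: Mapping[str, RankedDrugList],
    R: ReferenceSet,
    convention: str = "corrected",
) -> tuple["pandas.DataFrame", "pandas.DataFrame"]:
    """DSEA curves for several ranked lists against one reference set.

    Returns (long-format curve table, maxima summary) ready for plotting:
    the curve table has one row per (list, position) with the drug, match
    flag, tau, increment and running score; the summary has one row per list
    with its maximum score and position.
    """
    import pandas as pd

    curve_rows = []
    max_rows = []
    for name, lst in lists.items():
        curve = dsea_curve(lst, R, convention)
        for i, drug in enumerate(lst.drugs, start=1):
            curve_rows.append({
                "list": name, "position": i, "drug": drug,
                "is_match": curve.is_match[i - 1],
                "tau": curve.tau[i - 1],
                "increment": curve.increments[i - 1],
                "score": curve.scores[i],
            })
        max_rows.append({"list": name, "max_score": curve.max_score,
                         "max_position": curve.max_position,
                         "n": curve.n, "convention": convention})
    return pd.DataFrame(curve_rows), pd.DataFrame(max_rows)


def write_profile(curves: "pandas.DataFrame", path: str | Path) -> None:
    curves.to_csv(path, sep="\t", index=False)
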