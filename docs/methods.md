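# Methods

## The discovery model

`epilit` operationalizes literature-based discovery in its open form: a
disease A is linked to candidate drugs C through intermediate B-terms that
co-occur with drug names in individual documents. The ontologies supplying
the B-terms are treated strictly as flat term sets — class hierarchy,
axioms and cross-references are ignored, because the discovery step only
needs surface forms to match in text. Association strength is raw document
frequency: the number of documents in which a drug co-occurs with at least
one B-term of a given ontology, with repeated mentions inside one document
counting once. No statistical association measure (PMI, chi-square) is
layered on top; the ranking *is* the document-frequency order, with ties
broken lexicographically so runs are deterministic.

## Dictionaries and matching

Surface forms are normalized by case-folding, trimming, and tokenizing on
whitespace and punctuation (maximal alphanumeric runs); normalization is
idempotent. With stemming enabled, each form additionally contributes a
token-wise snowball (Porter2 English) stemmed entry — an *addition*, never a
replacement, so exact text always still matches. The Porter2 stemmer is
implemented inside the package from the published algorithm definition and
is unit-tested against hand-verified reference pairs.

Matching is leftmost-longest at token granularity, per dictionary: at each
token position the longest dictionary form matching a contiguous token
subsequence wins, the scan resumes after it, and within one dictionary no
two annotations overlap. Overlaps *across* dictionaries are allowed — a
drug name may sit inside a B-term span. Substring matches inside a token
are rejected. Annotations are stand-off records with 0-based, half-open
character offsets into the title-plus-abstract string (joined by a single
space); the slice identity `text[offset:offset+length] == matched_text`
is asserted property-style in the tests.

## The enrichment score

For a ranked list D = {d₁…d_N} and reference set R (|R| = S), the running
sum starts at x₀ = 0 and position i adds

* ln((S + τ)/(S − τ)) if dᵢ ∈ R (bonus),
* ln((N − τ)/(N + τ)) otherwise (penalty),

with τ the count of reference items among d₁…dᵢ (including dᵢ). The
adaptive τ makes late matches worth more and late misses cost more, which
keeps the statistic informative for short drug lists where a classical
GSEA-style fixed step would be nearly flat. The maximum Ψ\* over x₁…x_N and
its smallest attaining 1-based position k summarize the curve.

Two conventions are first-class. The defining formula can be read with the
bonus fraction as (S−τ)/(S+τ), which makes every "bonus" negative and
produces monotonically falling curves — inconsistent with the intended
bonus/penalty semantics. The default `corrected` convention inverts the
bonus fraction; `verbatim` computes the literal reading. Both are tested
against an independent step-by-step oracle. Degenerate cases: τ is clamped
to S−1 inside the bonus only, so the score stays finite after every
reference item has been found; an S = 1 reference set yields a zero bonus;
a list with no matches yields the identically-zero curve with k = 1 (each
penalty is then ln(N/N) = 0).

## Rank fusion

The consensus list minimizes the mean distance to the input lists over
orderings of the top-k union items. Default distance is the Spearman
footrule with absent items assigned virtual rank ℓ+1 for a length-ℓ list —
the standard top-k treatment; Kendall-style pairwise disagreement (ties at
the virtual rank counted as half-discordant mismatches) is available. The
underlying aggregation method in the original workflow is delegated to an
external cross-entropy Monte-Carlo implementation whose distance, k-rule
and hyperparameters are unspecified, so the exact published ordering is not
a reproduction target; the optimizer here is specified fully instead.

`exhaustive` enumerates all orderings (permitted to 8 items; the test-suite
oracle). `cemc` samples orderings from a per-position weight matrix
(sequential sampling without replacement, vectorized with the Gumbel-max
trick), keeps the best 10 % of 200 samples per iteration, re-estimates the
matrix with smoothing 0.7, and stops after 10 iterations without
improvement beyond 1e−6 (at most 100 iterations). The best-so-far objective
is recorded per iteration and is non-increasing by construction. On random
instances of ≤ 6 items and ≥ 3 lists the search recovers the exhaustive
optimum on all 100 seeded instances in the acceptance suite. `k="auto"`
grows k until the per-item objective stops improving by more than the
tolerance.

## Prioritization

Ranked lists are filtered to drugs holding at least one ATC code under a
prefix (default class `N`; `N03` = antiepileptics). Drugs missing from the
ATC map are dropped with a logged tally rather than raising — real drug
vocabularies are incomplete. The priority score is additive: one point per
reference list containing the drug (case-insensitive label match) plus one
for an N03 code, maximum 5. The relation-type annotation (treating /
potential / related / side-effect) is manual curation and is carried as a
pass-through field only.

## Ontology comparison

Concepts match when their normalized surface-form sets (label + synonyms)
intersect; matching uses case-insensitive exact string equality without
stemming, since stemming would merge genuinely distinct terms and inflate
the mapping. A concept is "shared" if it matches a concept of *another*
source, counted once regardless of how many foreign concepts it matches.
Explicit matches form graph edges annotated with their witnessing synonyms;
connected components capture implicit similarity (b₂ ~ b₃ through a common
neighbour b₁). Synonym-level reports count stored synonym strings per
source (labels excluded) but decide uniqueness and sharing on normalized
forms. Document-set overlap reports Venn cells for up to four named sets
(pairwise intersections beyond that), per-set sharing fractions, and corpus
coverage.

## Synthetic data

The fixtures module emulates the five input kinds at desk scale with exact
planted truth:

* **Corpora** — each document independently receives B-terms of each
  synthetic ontology with probability 0.6, and each drug with a planted
  per-drug probability (defaults strictly decreasing 0.8 → 0.05 over 10
  drugs, 500 documents, background drug rate 0.05 in documents without
  B-terms). Background text comes from a closed 24-word vocabulary checked
  for collisions against every planted term, and ≥ 20 % of planted terms
  are multi-word (including a three-token form) to exercise
  leftmost-longest matching. Ground-truth co-occurrence tables are tallied
  during generation and are recomputable by brute force; a fixed seed gives
  byte-identical output.
* **Term sources** — pairwise shared-concept counts are constructed, not
  sampled: each pair of sources shares exactly `round(fraction·n)` concepts
  through pair-specific bridge synonyms.
* **Reference sets** — a ranked list plus reference set with matches at
  exactly the requested positions, optionally padded with off-list items
  (allowing S > N to exercise the τ-clamp guard).

What the generators do *not* model: Medline's term-frequency distributions,
abbreviation ambiguity, hyphenation/spelling variants, and annotation noise.
Passing tests therefore demonstrate correctness of the counting, matching
and scoring machinery under clean planted conditions, not NER recall on
real biomedical text.

## Scale and numerics

The corpus pass is streaming with bounded per-document memory; artifacts
are plain JSON-Lines and TSV. Test corpora use 30–2000 documents (2000 for
the rank-recovery check, where planted probability gaps exceed five
binomial standard errors), fusion oracle instances ≤ 6 items, and overlap
oracles ≤ 50 concepts per source — sizes chosen so the full suite runs in
seconds while each check is still decisive. Ratios and percentages are
reported rounded (3 decimals for term-statistics tables, 2 for document
coverage figures, configurable). Score conservation is checked at 1e−9;
published percentage figures are matched at their printed precision.

## Known limitations

* No relation-type extraction: a co-occurrence says nothing about whether
  the drug treats, worsens, or merely co-occurs with the disease.
* Document frequency under-ranks rarely mentioned but relevant drugs.
* The ATC filter discards drugs without nervous-system codes even when a
  neurological effect is simply unrecorded.
* Dictionary NER misses surface forms absent from the ontologies
  (no language-model generalization).
* One published table's synonyms-per-concept row is internally inconsistent
  with its own concept/synonym counts for four of five ontologies; reports
  here always recompute ratios from loaded counts.
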