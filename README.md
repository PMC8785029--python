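# epilit

Ontology-driven literature-based discovery of candidate drugs for epilepsy.

`epilit` implements the Open Discovery Process (Swanson's ABC model) as a
tested, end-to-end pipeline: a disease **A** (epilepsy) is connected to
candidate drugs **C** through intermediate **B-terms** — the labels and
synonyms of epilepsy-specific ontologies — that co-occur with drug names in
the scientific literature, even when the disease and the drug never appear in
the same article. It is meant for text-mining and drug-repurposing
researchers who want each stage of such a pipeline as an importable,
independently testable component.

The stages, each an importable module with a thin CLI subcommand:

1. **termsource** — parse ontologies (OWL or a tabular dialect) and a drug
   vocabulary into flat concept sets; compile normalized lookup dictionaries,
   optionally expanded with snowball-stemmed variants.
2. **annotator** — dictionary NER over a JSON-Lines citation corpus
   (BioASQ/Medline dialect), leftmost-longest token matching, stand-off
   annotations (offset, length, matched text, concept, source).
3. **cooccurrence** — per-ontology document frequencies: a drug's count is
   the number of documents containing it together with at least one of the
   ontology's B-terms; ranked lists sort by descending count.
4. **prioritize** — ATC class filtering (class `N`, nervous system) and the
   0–5 priority score: one point per curated reference list (Lancet, DRUGSE,
   EFO, U2D) containing the drug, plus one for an antiepileptic (`N03`) code.
5. **rankfusion** — consensus top-k ordering of several ranked lists,
   minimizing the mean Spearman footrule (or Kendall) distance, by exhaustive
   enumeration (small unions) or cross-entropy Monte-Carlo search.
6. **dsea** — the Drug Set Enrichment Analysis running sum over a ranked
   list D = {d₁…d_N} against a reference set R = {r₁…r_S}:
   position *i* receives ln((S+τ)/(S−τ)) on a match and ln((N−τ)/(N+τ)) on a
   miss, with τ the number of reference drugs seen so far — an adaptive
   bonus/penalty that stays informative for short lists. The curve's maximum
   Ψ\* and its position *k* summarize enrichment.
7. **ontocompare** — cross-ontology concept matching by shared synonyms
   (explicit edges, implicit similarity via connected components), synonym
   reuse statistics, and document-set Venn overlaps.
8. **fixtures** — deterministic synthetic corpora, ontologies and reference
   sets with planted ground truth, so every stage is testable without the
   multi-million-citation corpus or the real ontology downloads.

## Worked example

Enrichment of a 6-drug ranked list whose reference matches sit at ranks
1, 2 and 4 (`python examples/03_enrichment_score.py`):

```
 i drug         match  tau  increment    score
 1 listdrug001  True     1     0.5108   0.5108
 2 listdrug002  True     2     1.0986   1.6094
 3 listdrug003  False    2    -0.6931   0.9163
 4 listdrug004  True     3     1.9459   2.8622
 5 listdrug005  False    3    -1.0986   1.7636
 6 listdrug006  False    3    -1.0986   0.6650
maximum enrichment 2.8622 at position k=4
```

Each match adds ln((S+τ)/(S−τ)) — here S = 4, so the third match at rank 4
adds ln(7/1) ≈ 1.9459 — and each miss subtracts ln((N+τ)/(N−τ)). The peak
Ψ\* ≈ 2.86 at k = 4 says the reference drugs are concentrated in the first
four ranks.

Fusion and prioritization of three conflicting ontology-derived rankings
(`python examples/04_fuse_and_prioritize.py`):

```
consensus order: ['ketamine', 'phenobarbital', 'morphine', 'diazepam']
mean footrule distance to inputs: 2.000
after ATC class-N filter: ['ketamine', 'phenobarbital', 'morphine', 'diazepam']
  ketamine       priority 0
  phenobarbital  priority 5
  morphine       priority 0
  diazepam       priority 4
```

Phenobarbital scores the maximum 5: it appears on all four reference lists
and carries an N03 (antiepileptic) ATC code — exactly the profile of an
established first-line drug, while priority-0 drugs are the repurposing
candidates worth manual inspection.

The other examples cover dictionary compilation (`01`), corpus annotation
and document-frequency ranking against planted truth (`02`), and
ontology comparison with explicit/implicit similarity (`05`). The whole
pipeline also runs from the shell: see `epilit --help` (subcommands
`build-dict`, `annotate`, `aggregate`, `filter`, `combine`, `score`,
`dsea`, `compare`, `docsets`, `simulate`, `run`).

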