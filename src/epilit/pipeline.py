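"""End-to-end orchestration: dictionaries -> NER -> ranking -> fusion -> scores.

A single streaming pass over the corpus produces stand-off annotations and
per-document presence summaries; everything downstream works from those
summaries. All artifacts are plain files (JSON Lines and TSV) in a run
directory, described by a manifest with input hashes and per-stage counts so
that a rerun with the same configuration and seed is byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotator import annotate_corpus, read_corpus
from .cooccurrence import aggregate_counts, rank_drugs, write_ranked_list
from .dsea import dsea_profile
from .ontocompare import concept_overlap, docset_overlap, export_mapping, synonym_overlap
from .prioritize import (build_final_table, filter_atc, load_atc_map,
                         load_reference_set, write_final_table)
from .rankfusion import FusionConfig, combine_lists
from .termsource import build_dictionary, load_term_source

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    corpus: Path
    ontology_paths: dict[str, Path]           # source_id -> file
    drug_vocabulary: Path
    atc_map: Path
    reference_lists: dict[str, Path]          # lancet/drugse/efo/u2d -> file
    out_dir: Path
    ontology_format: str = "tabular"
    stem: bool = True
    atc_prefix: str = "N"
    dsea_convention: str = "corrected"
    fusion: FusionConfig = field(default_factory=FusionConfig)
    seed: int = 2021

    def validate(self) -> None:
        paths = [self.corpus, self.drug_vocabulary, self.atc_map,
                 *self.ontology_paths.values(), *self.reference_lists.values()]
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for name, path in [("corpus", config.corpus),
                       ("drug_vocabulary", config.drug_vocabulary),
                       ("atc_map", config.atc_map),
                       *config.ontology_paths.items(),
                       *config.reference_lists.items()]:
        manifest["inputs"][str(name)] = _sha256(Path(path))

    def fail(stage: str, ident: str, exc: Exception) -> None:
        raise RuntimeError(f"pipeline stage {stage!r} failed on {ident!r}: {exc}") \
            from exc

    # 1. dictionaries
    sources = {}
    dicts = []
    for oid, path in sorted(config.ontology_paths.items()):
        try:
            sources[oid] = load_term_source(path, config.ontology_format,
                                            source_id=oid)
        except Exception as exc:
            fail("build-dict", str(path), exc)
        dicts.append(build_dictionary(sources[oid], stem=config.stem))
    try:
        drug_source = load_term_source(config.drug_vocabulary, "tabular",
                                       source_id="drugs", role="C")
    except Exception as exc:
        fail("build-dict", str(config.drug_vocabulary), exc)
    dicts.append(build_dictionary(drug_source, stem=config.stem))
    manifest["stages"]["build-dict"] = {
        oid: {"concepts": src.n_concepts, "synonyms": src.n_synonyms}
        for oid, src in {**sources, "drugs": drug_source}.items()
    }

    # 2. streaming annotation
    summaries = []
    n_docs = 0
    n_annotations = 0
    with open(out / "annotations.jsonl", "w", encoding="utf-8") as sink, \
            open(out / "summaries.jsonl", "w", encoding="utf-8") as sum_sink:
        for doc_id, annotations, summary in annotate_corpus(
                read_corpus(config.corpus), dicts, frozenset({"drugs"}), sink):
            n_docs += 1
            n_annotations += len(annotations)
            summaries.append(summary)
            sum_sink.write(summary.to_json() + "\n")
    manifest["stages"]["annotate"] = {"documents": n_docs,
                                      "annotations": n_annotations}

    # 3. per-ontology aggregation and ranking
    ranked = {}
    filtered = {}
    atc = load_atc_map(config.atc_map)
    known = frozenset(sources)
    for oid in sorted(sources):
        table = aggregate_counts(summaries, oid, known)
        lst = rank_drugs(table)
        ranked[oid] = lst
        write_ranked_list(lst, out / f"ranked_{oid}.tsv")
        filtered[oid] = filter_atc(lst, atc, config.atc_prefix)
        write_ranked_list(filtered[oid], out / f"ranked_{oid}_atc{config.atc_prefix}.tsv")
        manifest["stages"].setdefault("rank", {})[oid] = {
            "n_docs_b": table.n_docs_b, "n_docs_bc": table.n_docs_bc,
            "drugs": len(lst), "drugs_after_atc": len(filtered[oid]),
        }

    # 4. rank fusion over the nonempty filtered lists
    fusion_inputs = [lst for lst in filtered.values() if len(lst) > 0]
    if fusion_inputs:
        config.fusion.seed = config.seed
        fused = combine_lists(fusion_inputs, config.fusion)
        final = fused.ranking
        write_ranked_list(final, out / "ranked_final.tsv")
        manifest["stages"]["combine"] = {
            "k": fused.k, "objective": fused.objective,
            "method": fused.method, "distance": fused.distance,
        }
    else:
        from .cooccurrence import RankedDrugList
        final = RankedDrugList("combined", [], [])
        manifest["stages"]["combine"] = {"k": 0, "objective": 0.0}

    # 5. reference scoring + DSEA
    refsets = {name: load_reference_set(path, name)
               for name, path in config.reference_lists.items()}
    order = ["lancet", "drugse", "efo", "u2d"]
    ordered_refsets = [refsets[n] for n in order if n in refsets]
    if len(final) > 0 and len(ordered_refsets) == 4:
        records = build_final_table(final, filtered, ordered_refsets, atc)
        write_final_table(records, out / "final_table.tsv")
        manifest["stages"]["score"] = {"drugs": len(records)}
    else:
        manifest["stages"]["score"] = {"drugs": 0}

    union_items = frozenset().union(*(rs.items for rs in refsets.values())) \
        if refsets else frozenset()
    if union_items:
        from .prioritize import ReferenceSet
        union_ref = ReferenceSet("reference-union", union_items)
        profile_lists = {oid: lst for oid, lst in filtered.items() if len(lst)}
        if len(final) > 0:
            profile_lists["final"] = final
        if profile_lists:
            curves, maxima = dsea_profile(profile_lists, union_ref,
                                          config.dsea_convention)
            curves.to_csv(out / "dsea_curves.tsv", sep="\t", index=False)
            maxima.to_csv(out / "dsea_maxima.tsv", sep="\t", index=False)
            manifest["stages"]["dsea"] = {
                row["list"]: {"max_score": row["max_score"],
                              "k": int(row["max_position"])}
                for _, row in maxima.iterrows()
            }

    # 6. ontology comparison + document-set overlap
    if len(sources) >= 2:
        graph, concept_report = concept_overlap(list(sources.values()))
        syn_report = synonym_overlap(list(sources.values()))
        export_mapping(graph, out / "mapping.tsv")
        with open(out / "overlap_report.json", "w", encoding="utf-8") as fh:
            json.dump({"concepts": _jsonable(concept_report),
                       "synonyms": _jsonable(syn_report)}, fh, indent=2)
        manifest["stages"]["compare"] = {
            "shared_concepts": concept_report["shared_total"],
            "shared_synonym_forms": syn_report["shared_forms"],
        }
    doc_sets = {}
    for s in summaries:
        for oid in s.b_sources:
            doc_sets.setdefault(oid, set()).add(s.doc_id)
    if doc_sets:
        ds_report = docset_overlap(doc_sets, corpus_size=n_docs)
        with open(out / "docset_overlap.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(ds_report), fh, indent=2)
        manifest["stages"]["docsets"] = {"coverage_pct": ds_report.get("coverage_pct")}

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k) if not isinstance(k, str) else k: _jsonable(v)
                for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
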