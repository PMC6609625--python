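"""End-to-end pipeline: ingest → harmonize → classify → partition →
enrich → crossref → select, with byte-stable report writing.

Stages degrade gracefully: enrichment, cross-referencing and selection
run only when their inputs (annotations, tissue lists, evidence table)
are configured. A failing stage keeps the outputs of the stages before
it and re-raises with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .atlas import Atlas, build_atlas, ingest_dataset, read_id_list, \
    read_manifest, write_atlas
from .crossref import CrossrefResult, EvidenceTable, ShortlistEntry, \
    crossref_tissues, load_tissue_lists, select_candidates, write_shortlist
from .enrich import AnnotationTable, EnrichmentResult, enrich, \
    enrichment_frame, filter_evidence
from .idmap import load_mapping
from .venn import CategoryPartition, category_union_sets, exclusive_to, \
    venn_regions, write_region_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run."""

    manifest: Path
    ids_dir: Path
    mapping: Path
    out_dir: Path
    annotations: Optional[Path] = None
    annotations_format: str = "tsv"  # tsv | gaf
    tissue_lists: Optional[Path] = None
    evidence: Optional[Path] = None
    dimension: str = "stage_class"
    query_category: str = "early"
    policy: str = "first"
    alpha: float = 0.05
    top_k: int = 50
    adjust_globally: bool = False
    evidence_whitelist: Optional[set[str]] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("manifest", "ids_dir", "mapping", "annotations",
                     "tissue_lists", "evidence"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in sorted(vars(self).items())}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    atlas: Atlas
    partitions: dict[str, CategoryPartition] = field(default_factory=dict)
    exclusives: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    enrichment: Optional[dict[str, list[EnrichmentResult]]] = None
    crossref: Optional[CrossrefResult] = None
    shortlist: Optional[list[ShortlistEntry]] = None
    summary: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every configured stage and write reports to the run
    directory; returns the in-memory results."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        mapping = load_mapping(config.mapping)
        records = []
        for rec in read_manifest(config.manifest):
            ids_file = Path(config.ids_dir) / f"{rec.dataset_id}.txt"
            raw = read_id_list(ids_file) if ids_file.exists() else []
            if not ids_file.exists():
                logger.warning("no ID list for %s; ingesting as empty",
                               rec.dataset_id)
            records.append(ingest_dataset(raw, rec, mapping,
                                          policy=config.policy))
        atlas = build_atlas(records)
        write_atlas(atlas, out / "atlas.tsv")
        result = PipelineResult(atlas=atlas)

        stage = "partition"
        for dim in ("fraction_class", "stage_class"):
            sets = category_union_sets(atlas, dim)
            if not sets:  # empty manifest: empty partition, no regions
                result.partitions[dim] = CategoryPartition(dim, {}, {})
                result.exclusives[dim] = {}
                continue
            part = venn_regions(sets, dimension=dim)
            result.partitions[dim] = part
            write_region_report(part, out / f"venn_{dim}")
            result.exclusives[dim] = {c: exclusive_to(part, c)
                                      for c in sorted(sets)}

        query = set(result.exclusives.get(config.dimension, {})
                    .get(config.query_category, []))

        stage = "enrich"
        if config.annotations is not None:
            ann = (AnnotationTable.from_gaf(config.annotations)
                   if config.annotations_format == "gaf"
                   else AnnotationTable.from_simple_tsv(config.annotations))
            if config.evidence_whitelist:
                ann = filter_evidence(ann, config.evidence_whitelist)
            background = {g for g, _ in atlas.records}
            if query:
                result.enrichment = enrich(
                    query, background, ann, alpha=config.alpha,
                    top_k=config.top_k,
                    adjust_globally=config.adjust_globally)
                frame = enrichment_frame(result.enrichment)
                frame.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                             float_format="%.6g")

        stage = "crossref"
        if config.tissue_lists is not None and query:
            tissues = load_tissue_lists(config.tissue_lists)
            result.crossref = crossref_tissues(query, tissues)
            write_region_report(result.crossref.partition,
                                out / "crossref_tissues")

        stage = "select"
        if config.evidence is not None and query:
            evidence = EvidenceTable.from_tsv(config.evidence)
            result.shortlist = select_candidates(query, evidence)
            write_shortlist(result.shortlist, out / "shortlist")

        stage = "summary"
        result.summary = _summarize(config, result, query)
        (out / "summary.json").write_text(
            json.dumps(result.summary, indent=2, sort_keys=True) + "\n",
            encoding="utf-8")
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _summarize(config: RunConfig, result: PipelineResult,
               query: set[str]) -> dict:
    atlas = result.atlas
    summary = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_datasets": len(atlas.manifest),
        "n_presence_pairs": atlas.n_presence_pairs,
        "n_unique_proteins": len({g for g, _ in atlas.records}),
        "venn_regions": {
            dim: {"&".join(sig): len(m) for sig, m in part.regions.items()
                  if m}
            for dim, part in result.partitions.items()},
        "exclusive_counts": {
            dim: {c: len(genes) for c, genes in excl.items()}
            for dim, excl in result.exclusives.items()},
        "query_category": config.query_category,
        "n_query": len(query),
    }
    if result.enrichment is not None:
        summary["n_enriched_terms"] = {
            ns: len(rs) for ns, rs in result.enrichment.items()}
    if result.crossref is not None:
        summary["n_in_any_tissue"] = result.crossref.n_in_any
    if result.shortlist is not None:
        summary["shortlist"] = [e.gene_name for e in result.shortlist]
    return summary
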