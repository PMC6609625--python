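"""Synthetic multi-dataset detection-list generator with ground truth.

Emulates the statistical structure the exclusivity analysis assumes: a
shared core of ubiquitous milk proteins detected across all categories
(like the handful of major caseins and whey proteins every study
reports), category-exclusive planted sets (the biomarker analogue),
background proteins with random category membership, per-dataset
detection dropout, and identifier noise (synonym accessions that need
mapping, plus unmappable junk IDs). Every pipeline stage can then be
scored against the known truth. Presence lists only — the abundance and
missingness structure of real mass-spectrometry data is not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas import DatasetRecord, build_atlas, ingest_dataset
from .idmap import IdMappingTable
from .venn import category_union_sets, exclusive_to, venn_regions

DEFAULT_CATEGORIES = ("colostrum", "early", "peak", "mid", "drying_off")

# representative sampling time per standard stage label, used when the
# simulation is written out in the standard manifest format
_STAGE_ENCODING: dict[str, dict] = {
    "colostrum": {"dim": 2}, "early": {"dim": 10}, "peak": {"dim": 50},
    "mid": {"dim": 120}, "drying_off": {"dryoff_day": 3},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one simulated multi-study compendium.

    Defaults mirror a modest meta-analysis: a five-stage design with a
    few datasets per stage, a ubiquitous core, planted exclusive sets of
    the same order as real exclusivity findings, high but imperfect
    per-dataset detection and mild identifier noise.
    """

    n_proteins: int = 300
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_datasets_per_category: int = 3
    core_size: int = 20
    exclusive_per_category: int = 40
    p_detect: float = 0.9
    synonym_prob: float = 0.1
    unmapped_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.core_size + self.exclusive_per_category * len(self.categories)
        if planted > self.n_proteins:
            raise ValueError(
                f"core + exclusives ({planted}) exceed universe "
                f"({self.n_proteins})")
        for name in ("synonym_prob", "unmapped_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.p_detect <= 1:
            raise ValueError(f"p_detect must be in (0, 1], got {self.p_detect}")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate category labels")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    core: set[str]
    exclusives: dict[str, set[str]]  # category -> planted exclusive genes
    memberships: dict[str, set[str]]  # gene -> category subset
    raw_id_lists: dict[str, list[str]]  # dataset -> emitted raw IDs
    n_unmapped_emitted: dict[str, int]  # dataset -> junk-ID emissions

    def to_json(self) -> str:
        return json.dumps({
            "core": sorted(self.core),
            "exclusives": {c: sorted(s) for c, s in self.exclusives.items()},
            "memberships": {g: sorted(s) for g, s in
                            sorted(self.memberships.items())},
            "n_unmapped_emitted": self.n_unmapped_emitted,
        }, indent=2, sort_keys=True)


@dataclass
class Simulation:
    config: SyntheticConfig
    manifest: list[DatasetRecord]
    id_lists: dict[str, list[str]]
    mapping: IdMappingTable
    truth: SyntheticTruth


def _gene(i: int) -> str:
    return f"GENE{i:05d}"


def simulate(config: SyntheticConfig) -> Simulation:
    """Generate one compendium: manifest, per-dataset raw-ID lists, a
    full mapping table and the ground truth. Reproducible from the seed.

    Universe layout: the first ``core_size`` proteins are present in
    every category; the next ``exclusive_per_category`` blocks are
    planted per-category exclusives; the remainder are background
    proteins whose category memberships are independent Bernoulli(0.5)
    draws topped up to at least two categories, which populates the
    intermediate Venn regions while keeping the planted sets the only
    truly exclusive proteins. Each dataset of category c contains each protein whose
    membership includes c independently with probability ``p_detect``;
    each detection is emitted as an unmappable junk ID with probability
    ``unmapped_prob``, else as a synonym accession with probability
    ``synonym_prob``, else as the primary accession.
    """
    rng = np.random.default_rng(config.seed)
    cats = list(config.categories)
    genes = [_gene(i) for i in range(config.n_proteins)]

    mapping = IdMappingTable(source_tag=f"synthetic_seed{config.seed}")
    for i, g in enumerate(genes):
        mapping.add(f"ACC{i:05d}", g)
        mapping.add(f"SYN{i:05d}", g)

    core = set(genes[:config.core_size])
    exclusives: dict[str, set[str]] = {}
    pos = config.core_size
    for c in cats:
        exclusives[c] = set(genes[pos:pos + config.exclusive_per_category])
        pos += config.exclusive_per_category

    memberships: dict[str, set[str]] = {g: set(cats) for g in core}
    for c in cats:
        for g in exclusives[c]:
            memberships[g] = {c}
    for g in genes[pos:]:
        sub = {c for c in cats if rng.random() < 0.5}
        # background proteins span >= 2 categories so that the planted
        # sets are the only truly exclusive proteins in the universe
        while len(sub) < min(2, len(cats)):
            sub.add(cats[int(rng.integers(len(cats)))])
        memberships[g] = sub

    by_category: dict[str, list[int]] = {c: [] for c in cats}
    for i, g in enumerate(genes):
        for c in memberships[g]:
            by_category[c].append(i)

    manifest: list[DatasetRecord] = []
    id_lists: dict[str, list[str]] = {}
    n_junk: dict[str, int] = {}
    junk_counter = 0
    for c in cats:
        for r in range(config.n_datasets_per_category):
            ds = f"{c}_{r + 1}"
            raws: list[str] = []
            junk = 0
            for i in by_category[c]:
                if rng.random() >= config.p_detect:
                    continue
                u = rng.random()
                if u < config.unmapped_prob:
                    raws.append(f"JUNK{junk_counter:06d}")
                    junk_counter += 1
                    junk += 1
                elif u < config.unmapped_prob + config.synonym_prob:
                    raws.append(f"SYN{i:05d}")
                else:
                    raws.append(f"ACC{i:05d}")
            manifest.append(DatasetRecord(dataset_id=ds, source_ref="synthetic",
                                          stage_class=c))
            id_lists[ds] = raws
            n_junk[ds] = junk
    truth = SyntheticTruth(core=core, exclusives=exclusives,
                           memberships=memberships, raw_id_lists=dict(id_lists),
                           n_unmapped_emitted=n_junk)
    return Simulation(config=config, manifest=manifest, id_lists=id_lists,
                      mapping=mapping, truth=truth)


def recover_exclusives(sim: Simulation) -> dict[str, set[str]]:
    """Run the real pipeline over a simulation: ingest every raw-ID
    list, build the atlas, and read per-category exclusive sets off the
    Venn decomposition of the category union sets."""
    records = [ingest_dataset(sim.id_lists[d.dataset_id], d, sim.mapping)
               for d in sim.manifest]
    atlas = build_atlas(records)
    sets = category_union_sets(atlas, "stage_class",
                               categories=list(sim.config.categories))
    partition = venn_regions(sets, dimension="stage_class")
    return {c: set(exclusive_to(partition, c))
            for c in sim.config.categories}


def recovery_report(truth: SyntheticTruth,
                    recovered: dict[str, set[str]],
                    ) -> dict[str, dict[str, float]]:
    """Per-category precision/recall of exclusive-set recovery.

    precision = |recovered ∩ planted| / |recovered|,
    recall = |recovered ∩ planted| / |planted|; both defined as 1.0 when
    their denominator is 0.
    """
    if set(truth.exclusives) != set(recovered):
        raise ValueError(
            f"category labels differ: truth {sorted(truth.exclusives)} vs "
            f"recovered {sorted(recovered)}")
    out = {}
    for c, planted in truth.exclusives.items():
        rec = recovered[c]
        tp = len(rec & planted)
        out[c] = {
            "precision": tp / len(rec) if rec else 1.0,
            "recall": tp / len(planted) if planted else 1.0,
        }
    return out


def write_simulation(sim: Simulation, out_dir: str | Path) -> Path:
    """Write a simulation in the pipeline's input formats: manifest TSV,
    per-dataset ID lists, mapping TSV and a truth JSON.

    Requires standard stage labels as categories (they encode to the
    manifest's dim/dryoff_day columns); arbitrary labels are in-memory
    only.
    """
    unknown = [c for c in sim.config.categories if c not in _STAGE_ENCODING]
    if unknown:
        raise ValueError(
            f"categories {unknown} have no manifest encoding; use the "
            "standard stage labels to export files")
    out_dir = Path(out_dir)
    (out_dir / "ids").mkdir(parents=True, exist_ok=True)
    cols = ["dataset_id", "source_ref", "dim", "dryoff_day", "technique",
            "max_g", "acidification", "major_protein_depletion", "breed",
            "country"]
    lines = ["\t".join(cols)]
    for d in sim.manifest:
        enc = _STAGE_ENCODING[d.stage_class]
        lines.append("\t".join([
            d.dataset_id, d.source_ref, str(enc.get("dim", "")),
            str(enc.get("dryoff_day", "")), "centrifugation", "3000",
            "false", "false", "synthetic", "synthetic"]))
    (out_dir / "manifest.tsv").write_text("\n".join(lines) + "\n",
                                          encoding="utf-8")
    for ds, raws in sim.id_lists.items():
        (out_dir / "ids" / f"{ds}.txt").write_text(
            "\n".join(raws) + ("\n" if raws else ""), encoding="utf-8")
    map_lines = ["raw_id\tgene_name"]
    for raw in sorted(sim.mapping.entries):
        for gene in sim.mapping.entries[raw]:
            map_lines.append(f"{raw}\t{gene}")
    (out_dir / "mapping.tsv").write_text("\n".join(map_lines) + "\n",
                                         encoding="utf-8")
    (out_dir / "truth.json").write_text(sim.truth.to_json() + "\n",
                                        encoding="utf-8")
    return out_dir
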