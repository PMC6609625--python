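"""Presence/absence atlas of milk proteins across proteomics datasets.

The atlas is a long-format table of (gene_name, dataset_id) presence
pairs plus a manifest of dataset metadata. Identification is treated as
all-or-nothing: a protein is either reported by a dataset or it is not;
abundance is never modeled. Within each dataset, gene names reported
more than once are collapsed to a single presence record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .idmap import IdMappingTable, Policy, harmonize, normalize_symbol

logger = logging.getLogger(__name__)

#: prefix for retained unmappable identifiers (audit mode)
UNMAPPED_PREFIX = "UNMAPPED:"


@dataclass(frozen=True)
class IsolationDescriptor:
    """How a dataset's proteins were isolated from raw milk."""

    technique: str  # centrifugation | ultracentrifugation | cream_separation | sucrose_gradient
    max_g: Optional[float] = None
    acidification: bool = False
    major_protein_depletion: bool = False

    def __post_init__(self) -> None:
        if self.max_g is not None and self.max_g <= 0:
            raise ValueError(f"max_g must be > 0, got {self.max_g}")


@dataclass
class IngestStats:
    """Per-dataset provenance counters for one ingestion pass."""

    n_raw: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_after_dedup: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"n_raw": self.n_raw, "n_mapped": self.n_mapped,
                "n_unmapped": self.n_unmapped,
                "n_after_dedup": self.n_after_dedup}


@dataclass
class DatasetRecord:
    """One proteomics dataset: study metadata plus its deduplicated
    gene-name set."""

    dataset_id: str
    source_ref: str = ""
    dim: Optional[int] = None
    dryoff_day: Optional[int] = None
    method: Optional[IsolationDescriptor] = None
    breed: str = ""
    country: str = ""
    fraction_class: Optional[str] = None
    stage_class: Optional[str] = None
    gene_names: frozenset[str] = frozenset()
    ingest_stats: Optional[IngestStats] = None

    def __post_init__(self) -> None:
        if self.dim is not None and self.dryoff_day is not None:
            raise ValueError(
                f"dataset {self.dataset_id}: dim and dryoff_day are "
                "mutually exclusive")
        self.gene_names = frozenset(self.gene_names)


@dataclass
class Atlas:
    """Long-format presence records plus their dataset manifest."""

    records: list[tuple[str, str]] = field(default_factory=list)  # (gene, dataset)
    manifest: list[DatasetRecord] = field(default_factory=list)
    provenance: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.manifest]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset_id in manifest")
        known = set(ids)
        seen: set[tuple[str, str]] = set()
        for pair in self.records:
            if pair in seen:
                raise ValueError(f"duplicate presence pair {pair}")
            seen.add(pair)
            if pair[1] not in known:
                raise ValueError(
                    f"presence pair references unknown dataset {pair[1]!r}")

    @property
    def n_presence_pairs(self) -> int:
        return len(self.records)

    def dataset(self, dataset_id: str) -> DatasetRecord:
        for d in self.manifest:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with the classification columns joined on."""
        meta = {d.dataset_id: d for d in self.manifest}
        rows = [(g, ds, meta[ds].fraction_class, meta[ds].stage_class)
                for g, ds in self.records]
        return pd.DataFrame(
            rows, columns=["gene_name", "dataset_id",
                           "fraction_class", "stage_class"])


def ingest_dataset(raw_ids: Iterable[str], record: DatasetRecord,
                   mapping: IdMappingTable, policy: Policy = "first",
                   keep_unmapped: bool = False) -> DatasetRecord:
    """Map a dataset's raw identifier list to its deduplicated gene set.

    Each raw identifier is harmonized through *mapping*; identifiers with
    no mapping are excluded (counted in provenance) unless *keep_unmapped*
    retains them under the reserved ``UNMAPPED:`` prefix for audit.
    Gene names reported more than once in the dataset collapse to one.
    """
    raw_ids = [r for r in (s.strip() for s in raw_ids) if r]
    stats = IngestStats(n_raw=len(raw_ids))
    if not raw_ids:
        logger.warning("dataset %s: empty identifier list", record.dataset_id)
    genes: set[str] = set()
    for raw in raw_ids:
        names = harmonize(raw, mapping, policy=policy)
        if names:
            stats.n_mapped += 1
            genes.update(names)
        else:
            stats.n_unmapped += 1
            if keep_unmapped:
                genes.add(UNMAPPED_PREFIX + normalize_symbol(raw))
    stats.n_after_dedup = len(genes)
    return replace(record, gene_names=frozenset(genes), ingest_stats=stats)


def build_atlas(datasets: list[DatasetRecord]) -> Atlas:
    """Aggregate per-dataset gene sets into one presence atlas.

    The total number of presence pairs equals the sum of per-dataset
    gene-set sizes (within-dataset duplicates are already collapsed).
    """
    seen_ids: set[str] = set()
    for d in datasets:
        if d.dataset_id in seen_ids:
            raise ValueError(f"duplicate dataset_id {d.dataset_id!r}")
        seen_ids.add(d.dataset_id)
    manifest = sorted(datasets, key=lambda d: d.dataset_id)
    records = [(g, d.dataset_id) for d in manifest
               for g in sorted(d.gene_names)]
    provenance = {d.dataset_id: d.ingest_stats.as_dict()
                  for d in manifest if d.ingest_stats is not None}
    return Atlas(records=records, manifest=manifest, provenance=provenance)


def unique_proteins(atlas: Atlas) -> set[str]:
    """Union of gene names over all presence pairs (the nonredundant
    protein inventory of the atlas)."""
    return {g for g, _ in atlas.records}


# ---------------------------------------------------------------------------
# text-file interfaces

def read_id_list(path: str | Path) -> list[str]:
    """Read a per-dataset identifier list: one identifier per line,
    '#' comments and blank lines ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def _opt_int(cell: str) -> Optional[int]:
    return int(float(cell)) if cell.strip() else None


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell.strip() else None


def _bool(cell: str) -> bool:
    return cell.strip().lower() in ("true", "1", "yes")


def read_manifest(path: str | Path, classify: bool = True) -> list[DatasetRecord]:
    """Read a dataset manifest TSV into records.

    Required columns: dataset_id, source_ref, dim, dryoff_day, technique,
    max_g, acidification, major_protein_depletion, breed, country
    (empty cell = absent). Extra columns are ignored. With *classify*
    (default) fraction/stage classes are assigned from the default rules.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    required = {"dataset_id", "source_ref", "dim", "dryoff_day", "technique",
                "max_g", "acidification", "major_protein_depletion",
                "breed", "country"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        method = IsolationDescriptor(
            technique=row["technique"].strip(),
            max_g=_opt_float(row["max_g"]),
            acidification=_bool(row["acidification"]),
            major_protein_depletion=_bool(row["major_protein_depletion"]),
        )
        records.append(DatasetRecord(
            dataset_id=row["dataset_id"].strip(),
            source_ref=row["source_ref"].strip(),
            dim=_opt_int(row["dim"]),
            dryoff_day=_opt_int(row["dryoff_day"]),
            method=method,
            breed=row["breed"].strip(),
            country=row["country"].strip(),
        ))
    if classify:
        from .rules import classify_fraction, classify_stage
        records = [replace(r,
                           fraction_class=classify_fraction(r.method),
                           stage_class=classify_stage(r.dim, r.dryoff_day))
                   for r in records]
    return records


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    """Export the atlas as a long-format TSV plus a JSON provenance
    sidecar (``<path>.provenance.json``)."""
    path = Path(path)
    df = atlas.to_frame().sort_values(["dataset_id", "gene_name"])
    df.to_csv(path, sep="\t", index=False)
    sidecar = Path(str(path) + ".provenance.json")
    sidecar.write_text(json.dumps(atlas.provenance, indent=2, sort_keys=True)
                       + "\n", encoding="utf-8")


def read_atlas(path: str | Path) -> Atlas:
    """Re-ingest an exported atlas TSV (classes are taken as stored)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    groups: dict[str, dict[str, object]] = {}
    for _, row in df.iterrows():
        d = groups.setdefault(row["dataset_id"], {
            "fraction_class": row["fraction_class"] or None,
            "stage_class": row["stage_class"] or None,
            "genes": set()})
        d["genes"].add(row["gene_name"])
    manifest = [DatasetRecord(dataset_id=ds,
                              fraction_class=info["fraction_class"],
                              stage_class=info["stage_class"],
                              gene_names=frozenset(info["genes"]))
                for ds, info in groups.items()]
    return build_atlas(manifest)
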