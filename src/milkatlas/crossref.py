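"""Candidate cross-referencing and biomarker shortlisting.

The final screening steps for the exclusivity candidates: (1) compare
them against external tissue proteome lists (liver, adipose, mammary —
the key adaptive tissues of a lactating cow in negative energy balance)
and (2) apply declarative selection criteria over curated per-protein
evidence flags (pathway membership, literature support). The literature
and pathway-database mining behind those flags is inherently manual;
its per-protein outcome is the input here, not the process.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .idmap import normalize_symbol
from .venn import CategoryPartition, venn_regions

logger = logging.getLogger(__name__)

ENERGY_PATHWAYS = frozenset(
    {"gluconeogenesis", "ketone_metabolism", "oxidative_phosphorylation"})
PROLIFERATION_FLAG = "cell_proliferation"


@dataclass(frozen=True)
class EvidenceRow:
    gene_name: str
    tissue_hits: frozenset[str] = frozenset()
    pathway_flags: frozenset[str] = frozenset()
    literature_support: bool = False
    notes: str = ""


@dataclass
class EvidenceTable:
    """Curated per-candidate evidence; one row per gene name."""

    rows: dict[str, EvidenceRow] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, gene: str) -> EvidenceRow:
        """Row for *gene*; absent genes yield an all-false row (logged)."""
        key = normalize_symbol(gene)
        if key not in self.rows:
            logger.info("gene %s absent from evidence table; treated as "
                        "all-false", key)
            return EvidenceRow(gene_name=key)
        return self.rows[key]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EvidenceTable":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         keep_default_na=False)
        table = cls()
        for _, r in df.iterrows():
            gene = normalize_symbol(r["gene_name"])
            if gene in table.rows:
                raise ValueError(f"duplicate evidence row for {gene}")
            split = lambda cell: frozenset(
                t.strip() for t in cell.split(";") if t.strip())
            table.rows[gene] = EvidenceRow(
                gene_name=gene,
                tissue_hits=split(r.get("tissue_hits", "")),
                pathway_flags=split(r.get("pathway_flags", "")),
                literature_support=r.get("literature_support", "")
                .strip().lower() in ("true", "1", "yes"),
                notes=r.get("notes", ""))
        return table


def load_tissue_lists(path: str | Path) -> dict[str, set[str]]:
    """Read tissue → gene-set lists from a TSV with columns
    tissue, gene_name (extra columns such as citation keys ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    out: dict[str, set[str]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["tissue"].strip(), set()).add(
            normalize_symbol(r["gene_name"]))
    return out


@dataclass
class CrossrefResult:
    partition: CategoryPartition
    n_in_any: int
    not_in_any: set[str]


def crossref_tissues(candidates: set[str],
                     tissue_lists: dict[str, set[str]]) -> CrossrefResult:
    """Venn decomposition of the candidates over external tissue lists.

    Tissue sets are first restricted to the candidates; ``n_in_any``
    counts candidates found in at least one tissue list.
    """
    if not tissue_lists:
        raise ValueError("tissue_lists must be non-empty")
    restricted = {t: s & candidates for t, s in tissue_lists.items()}
    partition = venn_regions(restricted, dimension="tissue")
    in_any = set().union(*restricted.values())
    return CrossrefResult(partition=partition, n_in_any=len(in_any),
                          not_in_any=candidates - in_any)


@dataclass(frozen=True)
class SelectionCriteria:
    """Declarative shortlist rule: an energy-metabolism pathway flag or
    a cell-proliferation flag, plus literature support."""

    energy_pathways: frozenset[str] = ENERGY_PATHWAYS
    proliferation_flag: str = PROLIFERATION_FLAG
    require_literature: bool = True


@dataclass(frozen=True)
class ShortlistEntry:
    gene_name: str
    n_satisfied: int
    energy_pathway: bool
    proliferation: bool
    literature: bool
    rank: int


def select_candidates(candidates: set[str], evidence: EvidenceTable,
                      criteria: SelectionCriteria = SelectionCriteria(),
                      ) -> list[ShortlistEntry]:
    """Apply the selection criteria to every candidate.

    A candidate is shortlisted when it carries at least one
    energy-metabolism pathway flag OR the proliferation flag, AND (by
    default) has literature support. Entries are ranked by number of
    satisfied criteria, ties broken by gene name.
    """
    scored = []
    for gene in sorted(normalize_symbol(g) for g in candidates):
        row = evidence.get(gene)
        energy = bool(row.pathway_flags & criteria.energy_pathways)
        prolif = criteria.proliferation_flag in row.pathway_flags
        lit = row.literature_support
        selected = (energy or prolif) and (lit or not criteria.require_literature)
        if selected:
            scored.append((gene, energy + prolif + lit, energy, prolif, lit))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [ShortlistEntry(gene_name=g, n_satisfied=n, energy_pathway=e,
                           proliferation=p, literature=l, rank=i)
            for i, (g, n, e, p, l) in enumerate(scored, start=1)]


def write_shortlist(shortlist: list[ShortlistEntry], path: str | Path,
                    formats: tuple[str, ...] = ("tsv", "json")) -> None:
    path = Path(path)
    if "tsv" in formats:
        with open(path.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
            fh.write("rank\tgene_name\tn_satisfied\tenergy_pathway\t"
                     "proliferation\tliterature\n")
            for e in shortlist:
                fh.write(f"{e.rank}\t{e.gene_name}\t{e.n_satisfied}\t"
                         f"{str(e.energy_pathway).lower()}\t"
                         f"{str(e.proliferation).lower()}\t"
                         f"{str(e.literature).lower()}\n")
    if "json" in formats:
        payload = [{"rank": e.rank, "gene_name": e.gene_name,
                    "n_satisfied": e.n_satisfied,
                    "criteria": {"energy_pathway": e.energy_pathway,
                                 "proliferation": e.proliferation,
                                 "literature": e.literature}}
                   for e in shortlist]
        path.with_suffix(".json").write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8")
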