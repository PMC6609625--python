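"""Protein-identifier harmonization.

Proteomics publications report heterogeneous identifiers (UniProt
accessions, entry names, local database IDs). The atlas is keyed on gene
symbols, so every raw identifier is pushed through a user-supplied mapping
table before aggregation. Mapping tables are static TSV inputs; no live
web-service lookups are performed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

logger = logging.getLogger(__name__)

Policy = Literal["first", "all", "drop_ambiguous"]

_WS_RUN = re.compile(r"\s+")
# trailing isoform suffix on an accession-like token, e.g. "P62803-2"
_ISOFORM_SUFFIX = re.compile(r"^([A-Z0-9]{6,10})-\d+$")


def normalize_symbol(name: str) -> str:
    """Normalize a gene name or raw identifier: trim, collapse internal
    whitespace runs to a single space, uppercase.

    Matching throughout the package is case-insensitive; symbols such as
    "Bt.64131" or "Man8" are kept verbatim apart from this uniform casing.
    """
    return _WS_RUN.sub(" ", name.strip()).upper()


def normalize_identifier(raw_id: str) -> str:
    """Normalize a raw protein identifier for table lookup.

    Isoform suffixes ("-1", "-2") on accession-shaped identifiers are
    stripped: identifier-to-symbol conversion collapses isoforms to one
    gene name, so isoform accessions resolve to their parent entry.
    """
    norm = normalize_symbol(raw_id)
    m = _ISOFORM_SUFFIX.match(norm)
    return m.group(1) if m else norm


@dataclass
class IdMappingTable:
    """Mapping from normalized raw identifier to an ordered list of gene
    names (first-seen order; duplicate-free per key)."""

    entries: dict[str, list[str]] = field(default_factory=dict)
    source_tag: str = ""

    def __post_init__(self) -> None:
        for key, names in self.entries.items():
            if not names:
                raise ValueError(f"empty gene-name list for key {key!r}")
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate gene names for key {key!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, raw_id: str) -> bool:
        return normalize_identifier(raw_id) in self.entries

    def add(self, raw_id: str, gene_name: str) -> None:
        key = normalize_identifier(raw_id)
        gene = normalize_symbol(gene_name)
        names = self.entries.setdefault(key, [])
        if gene not in names:
            names.append(gene)

    @classmethod
    def from_pairs(cls, pairs: dict[str, str] | list[tuple[str, str]],
                   source_tag: str = "") -> "IdMappingTable":
        table = cls(source_tag=source_tag)
        items = pairs.items() if isinstance(pairs, dict) else pairs
        for raw, gene in items:
            table.add(raw, gene)
        return table


def load_mapping(path: str | Path, source_tag: str | None = None) -> IdMappingTable:
    """Load an identifier-to-gene-name mapping from a delimited text file.

    Requires a header with at least ``raw_id`` and ``gene_name`` columns
    (tab- or comma-delimited; an optional ``source`` column is ignored).
    Rows sharing a raw_id are merged preserving first-seen gene-name order;
    rows with a blank gene name are skipped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     comment="#", keep_default_na=False)
    missing = {"raw_id", "gene_name"} - set(df.columns)
    if missing:
        raise ValueError(
            f"mapping file {path} lacks required column(s): {sorted(missing)}")
    table = IdMappingTable(source_tag=source_tag or path.name)
    n_skipped = 0
    for raw, gene in zip(df["raw_id"], df["gene_name"]):
        if not raw.strip():
            n_skipped += 1
            continue
        if not gene.strip():
            n_skipped += 1
            logger.warning("mapping row with blank gene_name for %r skipped", raw)
            continue
        table.add(raw, gene)
    logger.info("loaded mapping %s: %d rows -> %d keys (%d skipped)",
                path.name, len(df), len(table), n_skipped)
    return table


def harmonize(raw_id: str, table: IdMappingTable,
              policy: Policy = "first") -> list[str]:
    """Resolve one raw identifier to gene names under an ambiguity policy.

    Unmapped identifiers yield ``[]``. Multi-mapped identifiers are
    resolved per *policy*: ``first`` keeps the first listed name (the
    default — identifier conversion assigns one symbol per protein entry),
    ``all`` keeps every name, ``drop_ambiguous`` drops the identifier.
    """
    if policy not in ("first", "all", "drop_ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    names = table.entries.get(normalize_identifier(raw_id))
    if names is None:
        return []
    if len(names) == 1:
        return list(names)
    if policy == "first":
        return [names[0]]
    if policy == "all":
        return list(names)
    logger.info("ambiguous identifier %r dropped (%d gene names)",
                raw_id, len(names))
    return []
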