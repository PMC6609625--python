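"""Set-exclusivity analysis over atlas categories.

A biomarker candidate here is a protein detected in exactly one category
(all-or-nothing identification): e.g. exclusively in early-lactation
milk across every dataset, whatever the milk fraction. This module
computes per-category union sets and the full Venn-region decomposition
by exact membership signature, from which exclusive sets are read off.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .atlas import Atlas

logger = logging.getLogger(__name__)

#: largest category count for which named Venn regions are enumerated
MAX_VENN_CATEGORIES = 6

Signature = tuple[str, ...]


@dataclass
class CategoryPartition:
    """Disjoint decomposition of category sets into Venn regions.

    ``regions`` maps a membership signature — the lexicographically
    sorted tuple of categories an element belongs to — to the set of
    elements with exactly that membership. Regions are pairwise disjoint
    and their union equals the union of all category sets.
    """

    dimension: str
    category_sets: dict[str, set[str]]
    regions: dict[Signature, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        """Check the disjoint-cover invariants; raise on violation."""
        total = set().union(*self.category_sets.values()) \
            if self.category_sets else set()
        covered: set[str] = set()
        n = 0
        for sig, members in self.regions.items():
            if tuple(sorted(sig)) != sig:
                raise AssertionError(f"non-canonical signature {sig}")
            if covered & members:
                raise AssertionError(f"region {sig} overlaps another region")
            covered |= members
            n += len(members)
        if covered != total or n != len(total):
            raise AssertionError("regions do not exactly cover the union")
        for cat, cat_set in self.category_sets.items():
            rebuilt = set().union(*(m for s, m in self.regions.items()
                                    if cat in s)) \
                if any(cat in s for s in self.regions) else set()
            if rebuilt != cat_set:
                raise AssertionError(f"regions do not rebuild category {cat!r}")

    def region_counts(self) -> dict[Signature, int]:
        return {sig: len(m) for sig, m in self.regions.items()}


def category_union_sets(atlas: Atlas, dimension: str,
                        categories: list[str] | None = None,
                        ) -> dict[str, set[str]]:
    """Per-category unique gene sets: the union of gene names over the
    datasets in each category (within-category duplicates collapse).

    *dimension* is ``"fraction_class"`` or ``"stage_class"``; declared
    *categories* with no datasets yield an empty set with a warning.
    """
    if dimension not in ("fraction_class", "stage_class"):
        raise ValueError(f"unknown dimension {dimension!r}")
    sets: dict[str, set[str]] = {c: set() for c in (categories or [])}
    for d in atlas.manifest:
        cat = getattr(d, dimension)
        if cat is None:
            raise ValueError(
                f"dataset {d.dataset_id} is not classified on {dimension}")
        sets.setdefault(cat, set()).update(d.gene_names)
    for cat, s in sets.items():
        if not s:
            logger.warning("category %r has no datasets on %s", cat, dimension)
    return sets


def venn_regions(category_sets: Mapping[str, set[str]],
                 dimension: str = "custom") -> CategoryPartition:
    """Decompose up to six category sets into their Venn regions.

    Every element is assigned to the single region whose signature is the
    exact set of categories containing it; all 2^k − 1 signatures with at
    least one member are represented (empty regions are kept explicit so
    reports mirror a full Venn diagram).
    """
    k = len(category_sets)
    if k == 0:
        raise ValueError("at least one category set is required")
    if k > MAX_VENN_CATEGORIES:
        raise ValueError(
            f"{k} categories exceed the {MAX_VENN_CATEGORIES}-set Venn "
            "limit; use upset_table() for a tabular decomposition")
    cats = sorted(category_sets)
    regions: dict[Signature, set[str]] = {}
    # all 2^k - 1 non-empty signatures, canonical order
    for mask in range(1, 2 ** k):
        sig = tuple(c for i, c in enumerate(cats) if mask >> i & 1)
        regions[sig] = set()
    for element in set().union(*category_sets.values()):
        sig = tuple(c for c in cats if element in category_sets[c])
        regions[sig].add(element)
    part = CategoryPartition(dimension=dimension,
                             category_sets={c: set(s) for c, s
                                            in category_sets.items()},
                             regions=regions)
    part.validate()
    return part


def upset_table(category_sets: Mapping[str, set[str]]) -> list[tuple[Signature, int]]:
    """Membership-signature counts for any number of categories
    (UpSet-style), sorted by descending count then signature."""
    counts: dict[Signature, int] = {}
    cats = sorted(category_sets)
    for element in set().union(*category_sets.values()) if category_sets else set():
        sig = tuple(c for c in cats if element in category_sets[c])
        counts[sig] = counts.get(sig, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def exclusive_to(partition: CategoryPartition, category: str) -> list[str]:
    """Gene names detected in *category* and nowhere else, sorted
    lexicographically."""
    if category not in partition.category_sets:
        raise KeyError(f"unknown category {category!r}")
    return sorted(partition.regions.get((category,), set()))


def write_region_report(partition: CategoryPartition, path: str | Path,
                        formats: tuple[str, ...] = ("tsv", "json")) -> None:
    """Write the region decomposition as TSV and/or JSON.

    TSV columns: signature ('&'-joined), n, genes (';'-joined, sorted).
    """
    path = Path(path)
    items = sorted(partition.regions.items())
    if "tsv" in formats:
        with open(path.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
            fh.write("signature\tn\tgenes\n")
            for sig, members in items:
                fh.write("&".join(sig) + f"\t{len(members)}\t"
                         + ";".join(sorted(members)) + "\n")
    if "json" in formats:
        payload = {
            "dimension": partition.dimension,
            "categories": sorted(partition.category_sets),
            "regions": [{"signature": list(sig), "n": len(members),
                         "genes": sorted(members)}
                        for sig, members in items],
        }
        path.with_suffix(".json").write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8")
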