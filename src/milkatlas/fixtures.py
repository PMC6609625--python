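"""Bundled reference tables and loaders.

Ships two small curated tables for the bovine milk proteome study
system — the 59 proteins detected exclusively in early-lactation milk
(with milk-fraction localization, protein IDs and descriptive names)
and the manifest of the 35 source proteomics datasets — plus the
curated per-candidate evidence flags and an explicitly synthetic
tissue-list stand-in. These drive the worked examples and the desk-scale
test surface; the full multi-thousand-protein atlas itself requires the
source studies' supplementary files, which are not redistributable here.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .atlas import DatasetRecord, read_manifest
from .enrich import AnnotationTable
from .idmap import IdMappingTable, normalize_symbol

MITO_LOCATION_TERM = "mitochondrion"
COMPLEX_PREFIXES = {
    "ATP synthase": "ATP synthase",
    "Cytochrome c oxidase": "cytochrome c oxidase",
    "60S ribosomal protein": "60S ribosomal protein",
}


def data_path(name: str) -> Path:
    return Path(resources.files("milkatlas").joinpath("data", name))


def early_lactation_table() -> pd.DataFrame:
    """The 59 early-lactation-exclusive proteins with normalized gene
    names, protein IDs, protein names and fraction localization."""
    df = pd.read_csv(data_path("early_lactation_proteins.tsv"), sep="\t",
                     dtype=str, keep_default_na=False)
    df["gene_name"] = df["gene_name"].map(normalize_symbol)
    return df


def early_lactation_genes() -> list[str]:
    return early_lactation_table()["gene_name"].tolist()


def fraction_localization_sets() -> dict[str, set[str]]:
    """Milk-fraction localization column as category sets (a protein
    localized to both fractions appears in both sets)."""
    sets: dict[str, set[str]] = {}
    for _, row in early_lactation_table().iterrows():
        for frac in row["fraction_localization"].split(";"):
            frac = frac.strip()
            key = "skimmed" if frac.lower() == "skimmed" else frac
            sets.setdefault(key, set()).add(row["gene_name"])
    return sets


def protein_name_annotations() -> AnnotationTable:
    """Location and complex annotations derived from the descriptive
    protein names: a 'mitochondrial' token marks the mitochondrion
    location; complex membership follows the protein-name prefix
    (ATP synthase / cytochrome c oxidase / 60S ribosomal protein)."""
    records = []
    for _, row in early_lactation_table().iterrows():
        gene, pname = row["gene_name"], row["protein_name"]
        if "mitochondrial" in pname.lower():
            records.append((gene, MITO_LOCATION_TERM, "mitochondrion",
                            "location", "name_token", "bovine"))
        for prefix, term in COMPLEX_PREFIXES.items():
            if pname.startswith(prefix):
                records.append((gene, term, term, "complex",
                                "name_prefix", "bovine"))
    return AnnotationTable.from_records(records)


def early_lactation_id_mapping() -> IdMappingTable:
    """Protein-ID → gene-name mapping extracted from the bundled table
    (handy for ingestion examples and round-trips)."""
    df = early_lactation_table()
    return IdMappingTable.from_pairs(
        list(zip(df["protein_id"], df["gene_name"])),
        source_tag="early_lactation_proteins")


def dataset_manifest(classify: bool = True) -> list[DatasetRecord]:
    """The 35-dataset manifest as records (classified by default)."""
    return read_manifest(data_path("dataset_manifest.tsv"), classify=classify)


def dataset_manifest_expected() -> pd.DataFrame:
    """Manifest with its curated fraction/stage class columns, for
    verifying the classification rules."""
    return pd.read_csv(data_path("dataset_manifest.tsv"), sep="\t",
                       dtype=str, keep_default_na=False)


def candidate_evidence_path() -> Path:
    return data_path("candidate_evidence.tsv")


def synthetic_tissue_lists_path() -> Path:
    return data_path("tissue_lists_synthetic.tsv")
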