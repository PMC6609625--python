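"""Annotation joins and over-representation analysis.

Gene sets pulled out of the atlas (e.g. the early-lactation-exclusive
proteins) are characterized against flat annotation tables: Gene
Ontology associations (GAF 2.x or a simplified TSV; used as given, no
DAG propagation), subcellular locations and protein-complex membership.

Over-representation of a term in a query set is tested with the exact
hypergeometric upper tail

    P(X >= x) = sum_{k=x}^{min(n,K)} C(K,k) C(N-K,n-k) / C(N,n)

where N is the annotated background size, K the background genes
carrying the term, n the annotated query size and x the query genes
carrying the term. Benjamini–Hochberg step-up adjustment controls the
FDR within each GO namespace, and terms with adjusted p below alpha are
reported up to a top-k cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp, lgamma, log
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC", "location", "complex")
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}

_COLUMNS = ["gene_name", "term_id", "term_label", "namespace",
            "evidence_code", "taxon"]


@dataclass
class AnnotationTable:
    """Flat gene → term association table.

    One row per (gene_name, term_id, taxon); the same gene/term pair may
    recur under different taxa (cross-species annotation transfer) and
    is counted once in enrichment.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation table lacks columns {sorted(missing)}")
        if (self.df["term_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty term_id in annotation table")
        if self.df.duplicated(["gene_name", "term_id", "taxon"]).any():
            raise ValueError("duplicate (gene_name, term_id, taxon) rows")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[tuple], ) -> "AnnotationTable":
        """Build from (gene, term_id, term_label, namespace, evidence,
        taxon) tuples; shorter tuples are padded with defaults."""
        rows = []
        for rec in records:
            rec = tuple(rec) + ("", "", "", "", "")[:6 - len(rec)]
            rows.append(rec[:6])
        df = pd.DataFrame(rows, columns=_COLUMNS).drop_duplicates(
            ["gene_name", "term_id", "taxon"])
        return cls(df.reset_index(drop=True))

    @classmethod
    def from_simple_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Read the simplified 5/6-column TSV (gene_name, term_id,
        term_label, namespace, evidence_code[, taxon])."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         keep_default_na=False)
        if "taxon" not in df.columns:
            df["taxon"] = ""
        return cls(df[_COLUMNS].drop_duplicates(
            ["gene_name", "term_id", "taxon"]).reset_index(drop=True))

    @classmethod
    def from_gaf(cls, path: str | Path) -> "AnnotationTable":
        """Read a GAF 2.x file (columns 2 object id is ignored; 3 symbol,
        5 GO id, 7 evidence, 9 aspect, 13 taxon are used)."""
        rows = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line or line.startswith("!"):
                continue
            f = line.split("\t")
            if len(f) < 13:
                logger.warning("short GAF line skipped: %r", line[:60])
                continue
            rows.append((f[2], f[4], f[4], _GAF_ASPECT.get(f[8], f[8]),
                         f[6], f[12]))
        return cls.from_records(rows)


def filter_evidence(table: AnnotationTable,
                    whitelist: set[str]) -> AnnotationTable:
    """Keep only associations whose evidence code is whitelisted."""
    if not whitelist:
        raise ValueError("evidence whitelist must be non-empty")
    kept = table.df[table.df["evidence_code"].isin(whitelist)]
    return AnnotationTable(kept.reset_index(drop=True))


def merge_taxa(tables: Sequence[AnnotationTable]) -> AnnotationTable:
    """Union annotation tables from several taxa.

    The same (gene, term) association contributed by multiple taxa keeps
    one provenance row per taxon but counts once logically — annotating
    against both bovine and human GO simply completes coverage.
    """
    if not tables:
        return AnnotationTable(pd.DataFrame(columns=_COLUMNS))
    df = pd.concat([t.df for t in tables], ignore_index=True)
    df = df.drop_duplicates(["gene_name", "term_id", "taxon"])
    return AnnotationTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# statistics

def _log_comb(a: int, b: int) -> float:
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def hypergeom_pvalue(x: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= x).

    X counts annotated genes in a size-n draw (the query) from a
    background of N genes of which K carry the term. Summation is done
    in log space for stability at large N.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(n, K)):
        raise ValueError(f"invalid hypergeometric bounds x={x} K={K} n={n} N={N}")
    if x == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    # support of X is [max(0, n-(N-K)), min(n, K)]; terms below it vanish
    terms = []
    for k in range(max(x, n - (N - K)), min(n, K) + 1):
        terms.append(_log_comb(K, k) + _log_comb(N - K, n - k) - log_denom)
    m = max(terms)
    total = m + log(sum(exp(t - m) for t in terms))
    return min(1.0, exp(total))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min over j with rank >= i of p_(j) * m / rank(j),
    capped at 1; monotone non-decreasing in the sorted raw order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out.tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term: contingency counts, raw/adjusted p and rank."""

    term_id: str
    term_label: str
    namespace: str
    x: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    rank: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.n, self.K)):
            raise ValueError("inconsistent contingency counts")
        if not (0 < self.p_raw <= 1) or self.p_adj < self.p_raw:
            raise ValueError("inconsistent p-values")


def enrich(query: set[str], background: set[str],
           annotations: AnnotationTable, alpha: float = 0.05,
           top_k: int = 50,
           namespaces: Sequence[str] = ("BP", "MF", "CC"),
           adjust_globally: bool = False,
           ) -> dict[str, list[EnrichmentResult]]:
    """Over-representation of annotation terms in *query* vs *background*.

    For each namespace the universe is the annotated subset of
    *background* (logged); every term with at least one query gene is
    tested, BH-adjusted within the namespace (or globally across the
    tested namespaces with *adjust_globally*), and terms with
    p_adj < *alpha* are reported up to *top_k*, ordered by
    (p_adj, p_raw, term_id).
    """
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    df = annotations.df[annotations.df["namespace"].isin(namespaces)]
    # global mode: pool namespaces for one BH family
    groups = [("all", df)] if adjust_globally \
        else [(ns, df[df["namespace"] == ns]) for ns in namespaces]
    results: dict[str, list[EnrichmentResult]] = {ns: [] for ns in namespaces}
    tested: list[tuple[str, str, str, int, int, int, int, float]] = []
    for _, sub in groups:
        annotated = set(sub["gene_name"])
        universe = background & annotated
        n_query = len(query & universe)
        N = len(universe)
        if n_query == 0:
            logger.warning("no annotated query genes in namespace group")
            continue
        pairs = sub[sub["gene_name"].isin(universe)] \
            .drop_duplicates(["gene_name", "term_id"])
        labels = dict(zip(pairs["term_id"], pairs["term_label"]))
        ns_of = dict(zip(pairs["term_id"], pairs["namespace"]))
        rows: list[tuple[str, str, str, int, int, int, int, float]] = []
        for term_id, genes in pairs.groupby("term_id")["gene_name"]:
            term_genes = set(genes)
            x = len(query & term_genes)
            if x == 0:
                continue
            K = len(term_genes)
            p = hypergeom_pvalue(x, K, n_query, N)
            rows.append((term_id, labels[term_id] or term_id,
                         ns_of[term_id], x, K, n_query, N, p))
        tested.extend(rows)
        if not adjust_globally:
            _finalize(rows, results, alpha, top_k)
    if adjust_globally:
        _finalize(tested, results, alpha, top_k)
    return results


def _finalize(rows, results, alpha, top_k):
    """BH-adjust one test family, filter, sort, rank and bin by namespace."""
    if not rows:
        return
    adj = bh_adjust([r[7] for r in rows])
    kept = [(r, a) for r, a in zip(rows, adj) if a < alpha]
    kept.sort(key=lambda ra: (ra[1], ra[0][7], ra[0][0]))
    by_ns: dict[str, list] = {}
    for r, a in kept:
        by_ns.setdefault(r[2], []).append((r, a))
    for ns, items in by_ns.items():
        for rank, (r, a) in enumerate(items[:top_k], start=1):
            results.setdefault(ns, []).append(EnrichmentResult(
                term_id=r[0], term_label=r[1], namespace=r[2], x=r[3],
                K=r[4], n=r[5], N=r[6], p_raw=r[7], p_adj=a, rank=rank))


def enrichment_frame(results: dict[str, list[EnrichmentResult]]) -> pd.DataFrame:
    """Flatten enrichment results into the report table."""
    rows = [(r.namespace, r.rank, r.term_id, r.term_label, r.x, r.K, r.n,
             r.N, r.p_raw, r.p_adj)
            for ns in sorted(results) for r in results[ns]]
    return pd.DataFrame(rows, columns=["namespace", "rank", "term_id",
                                       "term_label", "x", "K", "n", "N",
                                       "p_raw", "p_adj"])


# ---------------------------------------------------------------------------
# location and complex views

def flag_subcellular(genes: Sequence[str], annotations: AnnotationTable,
                     location_term: str) -> list[str]:
    """Subset of *genes* annotated with *location_term* in the location
    namespace, in input order."""
    loc = annotations.df[annotations.df["namespace"] == "location"]
    if location_term not in set(loc["term_id"]):
        raise KeyError(f"unknown location term {location_term!r}")
    carriers = set(loc[loc["term_id"] == location_term]["gene_name"])
    return [g for g in genes if g in carriers]


def assign_complexes(genes: Sequence[str],
                     annotations: AnnotationTable) -> dict[str, list[str]]:
    """Group *genes* by protein-complex membership (complex namespace);
    genes may belong to several complexes, members are sorted."""
    comp = annotations.df[annotations.df["namespace"] == "complex"]
    gene_set = set(genes)
    out: dict[str, list[str]] = {}
    for term_id, members in comp.groupby("term_id")["gene_name"]:
        hit = sorted(set(members) & gene_set)
        if hit:
            out[term_id] = hit
    return out
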