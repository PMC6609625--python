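"""Annotation tables and over-representation statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom
from statsmodels.stats.multitest import multipletests

from milkatlas.enrich import (AnnotationTable, assign_complexes, bh_adjust,
                              enrich, filter_evidence, flag_subcellular,
                              hypergeom_pvalue, merge_taxa)


def enumeration_pvalue(x, K, n, N):
    """Brute-force oracle: enumerate every size-n draw from N items of
    which the first K are marked; count draws with >= x marked."""
    marked = set(range(K))
    hits = sum(1 for draw in itertools.combinations(range(N), n)
               if len(marked & set(draw)) >= x)
    return hits / math.comb(N, n)


class TestHypergeom:
    def test_x_zero_is_one(self):
        assert hypergeom_pvalue(0, 5, 5, 10) == 1.0
        assert hypergeom_pvalue(0, 0, 0, 1) == 1.0

    def test_all_marked_draw(self):
        # drawing all 5 marked out of 10: 1 / C(10,5)
        assert hypergeom_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252,
                                                              abs=1e-15)

    @pytest.mark.parametrize("x,K,n,N", [
        (2, 4, 3, 9), (1, 2, 5, 8), (3, 6, 4, 10), (2, 3, 3, 7),
    ])
    def test_matches_enumeration(self, x, K, n, N):
        assert hypergeom_pvalue(x, K, n, N) == pytest.approx(
            enumeration_pvalue(x, K, n, N), abs=1e-12)

    def test_matches_scipy_survival_at_scale(self):
        # independent library cross-check away from enumeration range
        for x, K, n, N in [(12, 40, 50, 500), (3, 10, 20, 1000),
                           (8, 8, 30, 200)]:
            assert hypergeom_pvalue(x, K, n, N) == pytest.approx(
                scipy_hypergeom.sf(x - 1, N, K, n), rel=1e-10)

    @pytest.mark.parametrize("x,K,n,N", [
        (-1, 5, 5, 10), (6, 5, 5, 10), (2, 11, 5, 10), (2, 5, 11, 10),
    ])
    def test_bounds_enforced(self, x, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_pvalue(x, K, n, N)


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.01]) == [0.01]

    def test_hand_computed_step_up(self):
        # p_(i) * m / i = .04, .04, .04, .04 -> all collapse to 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])
        # sorted: .005*3/1=.015, .03*3/2=.045, .04*3/3=.04; cummin from
        # the largest rank collapses .045 -> .04
        assert bh_adjust([0.005, 0.04, 0.03]) == pytest.approx(
            [0.015, 0.04, 0.04])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1, size=40)
        ours = bh_adjust(list(p))
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(list(theirs), rel=1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [-0.1]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=150, deadline=None)
    def test_properties(self, p):
        adj = bh_adjust(p)
        assert all(a >= r - 1e-15 for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)
        # permutation equivariance
        perm = list(reversed(range(len(p))))
        adj_perm = bh_adjust([p[i] for i in perm])
        assert [adj[i] for i in perm] == pytest.approx(adj_perm)
        # monotone in the sorted raw order
        order = sorted(range(len(p)), key=lambda i: p[i])
        ranked = [adj[i] for i in order]
        assert all(a <= b + 1e-15 for a, b in zip(ranked, ranked[1:]))

    def test_fully_collapsed_vectors_are_fixed_points(self):
        # when step-up collapses every value to the same adjusted level
        # (maximal ties), re-adjusting changes nothing
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert bh_adjust(adj) == pytest.approx(adj)
        assert bh_adjust([0.5] * 6) == pytest.approx([0.5] * 6)


def _annotation(rows):
    return AnnotationTable.from_records(rows)


class TestAnnotationOps:
    def test_filter_whitelist_identity_and_oracle(self):
        rows = [("G1", "t1", "", "BP", "IDA", "bovine"),
                ("G2", "t1", "", "BP", "IEA", "bovine"),
                ("G3", "t2", "", "MF", "EXP", "bovine")]
        table = _annotation(rows)
        all_codes = {"IDA", "IEA", "EXP"}
        assert len(filter_evidence(table, all_codes)) == 3
        kept = filter_evidence(table, {"EXP", "IDA"})
        # row-by-row oracle
        expected = [r for r in rows if r[4] in {"EXP", "IDA"}]
        assert len(kept) == len(expected)
        assert set(kept.df["gene_name"]) == {r[0] for r in expected}

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            filter_evidence(_annotation([]), set())

    def test_merge_with_empty_is_identity(self):
        t = _annotation([("G1", "t1", "", "BP", "IDA", "bovine")])
        merged = merge_taxa([t, _annotation([])])
        assert len(merged) == len(t)

    def test_merge_unions_terms_across_taxa(self):
        bovine = _annotation([("G1", "t1", "", "BP", "IDA", "bovine")])
        human = _annotation([("G1", "t2", "", "BP", "IDA", "human")])
        merged = merge_taxa([bovine, human])
        assert set(merged.df["term_id"]) == {"t1", "t2"}

    def test_duplicate_association_counts_once_keeps_provenance(self):
        bovine = _annotation([("G1", "t1", "", "BP", "IDA", "bovine")])
        human = _annotation([("G1", "t1", "", "BP", "IDA", "human")])
        merged = merge_taxa([bovine, human])
        assert len(merged) == 2  # one provenance row per taxon
        logical = merged.df.drop_duplicates(["gene_name", "term_id"])
        assert len(logical) == 1

    def test_gaf_reader(self, tmp_path):
        gaf = tmp_path / "test.gaf"
        gaf.write_text(
            "!gaf-version: 2.2\n"
            "UniProtKB\tP1\tCSN2\t\tGO:0005615\tREF\tIDA\t\tC\t"
            "Beta-casein\t\tprotein\ttaxon:9913\t20190101\tDB\t\t\n")
        table = AnnotationTable.from_gaf(gaf)
        assert len(table) == 1
        row = table.df.iloc[0]
        assert (row["gene_name"], row["term_id"], row["namespace"],
                row["evidence_code"]) == ("CSN2", "GO:0005615", "CC", "IDA")


class TestEnrich:
    def test_query_equals_background_reports_nothing(self):
        rows = [(f"G{i}", "t1", "", "BP", "IDA", "b") for i in range(6)]
        table = _annotation(rows)
        genes = {f"G{i}" for i in range(6)}
        results = enrich(genes, genes, table)
        assert results["BP"] == []

    def test_closed_form_perfect_pullout(self):
        # background 20 genes all BP-annotated, term covers 5, query = those 5
        rows = [(f"G{i}", "bg_term", "", "BP", "IDA", "b") for i in range(20)]
        rows += [(f"G{i}", "hit", "", "BP", "IDA", "b") for i in range(5)]
        table = _annotation(rows)
        background = {f"G{i}" for i in range(20)}
        results = enrich({f"G{i}" for i in range(5)}, background, table)
        hit = [r for r in results["BP"] if r.term_id == "hit"][0]
        assert hit.p_raw == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert hit.rank == 1

    def test_singleton_query_praw_is_K_over_N(self):
        rows = [(f"G{i}", "t1", "", "BP", "IDA", "b") for i in range(8)]
        rows += [(f"G{i}", "t2", "", "BP", "IDA", "b") for i in range(20)]
        table = _annotation(rows)
        background = {f"G{i}" for i in range(20)}
        results = enrich({"G0"}, background, table, alpha=1.1, top_k=50)
        by_term = {r.term_id: r for r in results["BP"]}
        assert by_term["t1"].p_raw == pytest.approx(8 / 20)
        assert by_term["t2"].p_raw == pytest.approx(1.0)

    def test_query_outside_background_is_error(self):
        with pytest.raises(ValueError):
            enrich({"X"}, {"Y"}, _annotation([]))

    def test_unannotated_query_is_empty_with_warning(self, caplog):
        table = _annotation([("G1", "t1", "", "BP", "IDA", "b")])
        results = enrich({"Z"}, {"Z", "G1"}, table)
        assert results["BP"] == []
        assert any("no annotated query genes" in r.message
                   for r in caplog.records)

    def test_ranks_contiguous_and_sorted(self):
        rng = np.random.default_rng(5)
        rows = []
        genes = [f"G{i}" for i in range(60)]
        for t in range(12):
            for g in rng.choice(genes, size=15, replace=False):
                rows.append((g, f"t{t}", "", "BP", "IEA", "b"))
        table = _annotation(rows)
        query = set(genes[:12])
        results = enrich(query, set(genes), table, alpha=1.1)
        ranks = [r.rank for r in results["BP"]]
        assert ranks == list(range(1, len(ranks) + 1))
        adj = [r.p_adj for r in results["BP"]]
        assert adj == sorted(adj)

    def test_planted_term_ranks_first(self):
        """A strongly enriched planted term should top the ranking in
        >= 95% of simulated queries."""
        rng = np.random.default_rng(2024)
        genes = [f"G{i:03d}" for i in range(200)]
        rows = [(g, "planted", "", "BP", "IEA", "b") for g in genes[:30]]
        for t in range(10):
            for g in rng.choice(genes, size=30, replace=False):
                rows.append((g, f"noise{t}", "", "BP", "IEA", "b"))
        rows += [(g, "universe", "", "BP", "IEA", "b") for g in genes]
        table = _annotation(rows)
        background = set(genes)
        wins = 0
        for _ in range(200):
            query = set(rng.choice(genes[:30], size=15, replace=False))
            query |= set(rng.choice(genes, size=5, replace=False))
            results = enrich(query, background, table, alpha=1.1)
            top = min(results["BP"], key=lambda r: (r.p_adj, r.p_raw))
            wins += top.term_id == "planted"
        assert wins >= 190


class TestLocationAndComplex:
    def test_mitochondrial_flagging(self, early_genes, name_annotations):
        flagged = flag_subcellular(early_genes, name_annotations,
                                   "mitochondrion")
        assert len(flagged) == 15
        assert {"ACAT1", "SDHA", "UQCRC1", "IVD", "PCK2"} <= set(flagged)

    def test_unknown_location_term_is_error(self, name_annotations):
        with pytest.raises(KeyError):
            flag_subcellular(["ACAT1"], name_annotations, "nucleolus")

    def test_flagging_identity_on_exact_set(self, early_genes,
                                            name_annotations):
        flagged = flag_subcellular(early_genes, name_annotations,
                                   "mitochondrion")
        assert flag_subcellular(flagged, name_annotations,
                                "mitochondrion") == flagged

    def test_empty_annotation_gives_empty_subset(self):
        empty = AnnotationTable.from_records(
            [("G1", "mitochondrion", "", "location", "", "")])
        assert flag_subcellular(["G2"], empty, "mitochondrion") == []

    def test_complex_grouping_oracle(self):
        rows = [("G1", "cplxA", "", "complex", "", ""),
                ("G2", "cplxA", "", "complex", "", ""),
                ("G2", "cplxB", "", "complex", "", ""),
                ("G3", "cplxB", "", "complex", "", "")]
        groups = assign_complexes(["G1", "G2", "G3"], _annotation(rows))
        assert groups == {"cplxA": ["G1", "G2"], "cplxB": ["G2", "G3"]}

    def test_no_complex_annotations(self):
        assert assign_complexes(["G1"], _annotation([])) == {}
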