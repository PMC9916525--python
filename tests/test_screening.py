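"""Screens: count filter semantics, group set algebra, per-line top-k."""

import pandas as pd
import pytest

from ipscmine import (
    CountFilterSpec,
    MineParams,
    call_de,
    compare_groups,
    count_filter,
    group1_screen,
    group2_screen,
    group3_supplementary,
    select_main_subdatasets,
    upregulated_genes,
)
from ipscmine.io_formats import AnnotationCatalog, CountMatrix, GeneList
from ipscmine.errors import InputError
from ipscmine.screening import ScreenSet


def _matrix(rows: dict[str, list[int]], n_lines: int) -> CountMatrix:
    samples = ["B"] + [f"L{i}" for i in range(1, n_lines + 1)]
    counts = pd.DataFrame(rows, index=samples).T.astype("int64")
    counts.index.name = "gene_id"
    roles = {"B": "baseline", **{s: "line" for s in samples[1:]}}
    return CountMatrix(counts=counts, roles=roles)


class TestCountFilter:
    def test_low_baseline_high_lines_retained(self):
        m = _matrix({"GOOD": [0, 100, 100, 100]}, 3)
        assert count_filter(["GOOD"], m, CountFilterSpec()) == {"GOOD"}

    def test_baseline_boundary_is_inclusive_at_50(self):
        m = _matrix({"AT50": [50, 100, 100, 100], "AT51": [51, 100, 100, 100]}, 3)
        out = count_filter(["AT50", "AT51"], m, CountFilterSpec())
        assert out == {"AT50"}

    def test_mean_and_all_lines_aggregations_differ_on_borderline_gene(self):
        # lines (19, 21, 25): mean 21.67 >= 20 but one line below 20
        m = _matrix({"EDGE": [50, 19, 21, 25]}, 3)
        assert count_filter(["EDGE"], m, CountFilterSpec(aggregation="mean")) == {
            "EDGE"
        }
        assert (
            count_filter(["EDGE"], m, CountFilterSpec(aggregation="all_lines"))
            == frozenset()
        )
        assert count_filter(
            ["EDGE"], m, CountFilterSpec(aggregation="at_least_k", k=2)
        ) == {"EDGE"}

    def test_unknown_gene_named_in_error(self):
        m = _matrix({"A": [0, 30, 30, 30]}, 3)
        with pytest.raises(InputError, match="GHOST"):
            count_filter(["GHOST"], m, CountFilterSpec())

    def test_idempotent(self, study):
        matrix, *_ = study
        spec = CountFilterSpec()
        once = count_filter(matrix.gene_ids, matrix, spec)
        assert count_filter(once, matrix, spec) == once

    @pytest.mark.parametrize("aggregation", ["mean", "all_lines", "any_line"])
    def test_monotone_in_thresholds(self, study, aggregation):
        matrix, *_ = study
        universe = matrix.gene_ids
        base = count_filter(
            universe, matrix, CountFilterSpec(aggregation=aggregation)
        )
        stricter = count_filter(
            universe, matrix, CountFilterSpec(min_line=40, aggregation=aggregation)
        )
        looser = count_filter(
            universe, matrix,
            CountFilterSpec(max_baseline=200, aggregation=aggregation),
        )
        assert stricter <= base <= looser


def _toy_screen_inputs():
    """3-line toy instance small enough to enumerate by hand."""
    m = _matrix(
        {
            "UPSEL": [5, 60, 70, 80],      # up, in selected term, passes counts
            "UPNOSEL": [5, 60, 70, 80],    # up, no selected term
            "UPHIGHBASE": [500, 4000, 4000, 4000],  # up but baseline too high
            "FLAT": [50, 50, 50, 50],      # not up
            "IND1": [10, 90, 90, 90],      # inducible gene itself, up
            "DOWNSUB": [40, 2, 2, 2],      # subdataset member, down
            "FILL": [1000, 1000, 1000, 1000],
        },
        3,
    )
    de = call_de(m, significance_on="p")
    cat = AnnotationCatalog()
    cat.add("GO-process", "SEL", "selected", ["UPSEL", "UPHIGHBASE", "FLAT"])
    cat.add("GO-process", "OTHER", "not selected", ["UPNOSEL"])
    cat.add("KEGG-pathway", "SUB", "inducible-bearing", ["IND1", "DOWNSUB", "UPSEL"])
    selected = pd.DataFrame(
        [{"level": "GO-process", "term_id": "SEL", "p": 1e-4}]
    )
    return m, de, cat, selected


class TestGroupScreens:
    def test_group1_hand_enumeration(self):
        m, de, cat, selected = _toy_screen_inputs()
        out = group1_screen(de, selected, cat, m, CountFilterSpec())
        assert out.genes == {"UPSEL"}
        assert "UPSEL" in out.provenance
        assert out.provenance["UPSEL"]["terms"] == ["SEL"]

    def test_group1_empty_terms_empty_set(self):
        m, de, cat, _ = _toy_screen_inputs()
        out = group1_screen(de, pd.DataFrame(), cat, m, CountFilterSpec())
        assert out.genes == frozenset()

    def test_subdataset_selection_hand_enumeration(self):
        _m, _de, cat, _sel = _toy_screen_inputs()
        inducible = GeneList.from_symbols(["IND1", "NOTDETECTED"])
        subs = select_main_subdatasets(
            inducible, cat, detected=["IND1", "UPSEL", "DOWNSUB"],
            min_inducible_per_term=1,
        )
        assert subs.term_id.tolist() == ["SUB"]
        assert subs.iloc[0].inducible_genes == "IND1"

    def test_term_without_inducible_genes_never_selected(self):
        _m, _de, cat, _sel = _toy_screen_inputs()
        inducible = GeneList.from_symbols(["UPNOSEL"])  # only in OTHER
        subs = select_main_subdatasets(
            inducible, cat, detected=["UPNOSEL"], min_inducible_per_term=1
        )
        assert "SUB" not in set(subs.term_id) and "SEL" not in set(subs.term_id)

    def test_group2_hand_enumeration(self):
        m, de, cat, _sel = _toy_screen_inputs()
        subs = pd.DataFrame([{"level": "KEGG-pathway", "term_id": "SUB",
                              "n_inducible": 1}])
        out = group2_screen(de, subs, cat, m, CountFilterSpec())
        # SUB = {IND1, DOWNSUB, UPSEL}; DOWNSUB is down-regulated
        assert out.genes == {"IND1", "UPSEL"}

    def test_groups_subset_of_upregulated_and_count_filtered(self, study):
        matrix, catalog, _p, inducible, _t = study
        de = call_de(matrix)
        spec = CountFilterSpec()
        allowed = upregulated_genes(de, 1) & count_filter(
            upregulated_genes(de, 1), matrix, spec
        )
        from ipscmine.de_stats import enrich, select_top_terms

        enr = enrich(upregulated_genes(de, 1), catalog, matrix.gene_universe())
        sel = select_top_terms(enr)
        g1 = group1_screen(de, sel, catalog, matrix, spec)
        subs = select_main_subdatasets(inducible, catalog, matrix.gene_universe())
        g2 = group2_screen(de, subs, catalog, matrix, spec)
        assert g1.genes <= allowed and g2.genes <= allowed

    def test_group1_recovers_planted_members_exactly(self, study):
        """On synthetic truth, group1 equals the direct set evaluation of
        (selected-term members) & (up genes) & (count-filtered genes)."""
        matrix, catalog, _p, _i, truth = study
        de = call_de(matrix)
        spec = CountFilterSpec()
        from ipscmine.de_stats import enrich, select_top_terms

        enr = enrich(upregulated_genes(de, 1), catalog, matrix.gene_universe())
        sel = select_top_terms(enr)
        members = set()
        for _, row in sel.iterrows():
            members |= catalog.terms(row.level)[row.term_id].genes
        expected = count_filter(
            members & upregulated_genes(de, 1), matrix, spec
        )
        g1 = group1_screen(de, sel, catalog, matrix, spec)
        assert g1.genes == expected
        assert truth.planted_up & members & g1.genes == g1.genes & truth.planted_up


class TestGroup3Supplementary:
    def test_fewer_qualifying_than_k_takes_all(self):
        m, de, _cat, _sel = _toy_screen_inputs()
        out = group3_supplementary(de, m, CountFilterSpec(), top_k=30)
        # qualifying up genes passing counts: UPSEL, UPNOSEL, IND1
        assert out.genes == {"UPSEL", "UPNOSEL", "IND1"}

    def test_equal_counts_tie_broken_lexicographically(self):
        m = _matrix(
            {"AAA": [0, 50, 50], "BBB": [0, 50, 50], "CCC": [0, 40, 40],
             "FILL": [900, 900, 900]},
            2,
        )
        de = call_de(m, significance_on="p")
        out = group3_supplementary(de, m, CountFilterSpec(), top_k=1)
        assert out.genes == {"AAA"}

    def test_union_matches_per_line_sort_oracle(self, small_study):
        _cfg, (matrix, _c, _p, _i, _t) = small_study
        de = call_de(matrix)
        spec = CountFilterSpec()
        out = group3_supplementary(de, matrix, spec, top_k=5)
        qualifying = count_filter(upregulated_genes(de, 1), matrix, spec)
        expected: set[str] = set()
        up = de[de.direction == "up"]
        for line in matrix.line_samples:
            genes = sorted(
                set(up[up.line_id == line].gene_id) & qualifying,
                key=lambda g: (-int(matrix.counts.at[g, line]), g),
            )
            expected |= set(genes[:5])
        assert out.genes == expected


class TestCompareGroups:
    def _sset(self, label, genes):
        return ScreenSet(label, frozenset(genes), {}, {})

    def test_identical_sets_jaccard_one(self):
        report = compare_groups(self._sset("a", "ABC"), self._sset("b", "ABC"))
        assert report["jaccard"] == 1.0

    def test_disjoint_sets_jaccard_zero(self):
        report = compare_groups(self._sset("a", "AB"), self._sset("b", "CD"))
        assert report["jaccard"] == 0.0

    def test_partial_overlap_arithmetic(self):
        report = compare_groups(
            self._sset("a", ["X", "Y", "Z"]), self._sset("b", ["Y", "Z", "U", "V"])
        )
        assert report["intersection"] == 2
        assert report["jaccard"] == pytest.approx(2 / 5)
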