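import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactpath.annotation import (
    AnnotationError,
    GeneRecord,
    Pathway,
    SnpMap,
    SnpSet,
    exclude_chromosome,
    gene_pair_distances,
    load_gene_table,
    load_pathways_gmt,
    packaged_gene_table,
    packaged_gene_universe,
    packaged_pathways,
    pathway_overlap,
    pathway_snp_set,
    snps_in_window,
)


@pytest.fixture(scope="module")
def toy_map() -> SnpMap:
    pos = [899_999, 900_000, 1_000_000, 1_025_000, 1_150_000, 1_150_001]
    return SnpMap([f"s{i}" for i in range(len(pos))], ["1"] * len(pos), pos)


class TestGeneTableParsing:
    def test_packaged_tables_have_printed_gene_counts(self):
        assert len(packaged_gene_table("mammary_development")) == 64
        assert len(packaged_gene_table("prolactin_signalling")) == 27
        assert len(packaged_gene_table("involution")) == 40

    def test_ghr_row_coordinates(self):
        ghr = {g.symbol: g for g in packaged_gene_table("mammary_development")}["GHR"]
        assert (ghr.chrom, ghr.start, ghr.stop) == ("20", 31790736, 32299996)

    def test_empty_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(AnnotationError):
            load_gene_table(p)

    def test_malformed_coordinate_names_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("symbol\tchrom\tstart\tstop\nOK\t1\t10\t20\nBAD\t1\txx\t30\n")
        with pytest.raises(AnnotationError, match="line 3"):
            load_gene_table(p)

    def test_start_after_stop_is_a_validation_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("symbol\tchrom\tstart\tstop\nG\t1\t30\t10\n")
        with pytest.raises(AnnotationError, match="start"):
            load_gene_table(p)

    def test_duplicate_symbol_is_reported(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "symbol\tchrom\tstart\tstop\nG\t1\t1\t5\nG\t2\t1\t5\n"
        )
        with pytest.raises(AnnotationError, match="G"):
            load_gene_table(p)

    def test_summary_rows_are_skipped(self, tmp_path):
        p = tmp_path / "summ.tsv"
        p.write_text("symbol\tchrom\tstart\tstop\nG\t1\t1\t5\nN = 1\t\t\t\n")
        assert len(load_gene_table(p)) == 1

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("pw\tdesc\tA\tB\tC\n")
        (pw,) = load_pathways_gmt(p)
        assert pw.genes == ("A", "B", "C")


class TestWindows:
    def test_window_boundaries_are_inclusive(self, toy_map):
        gene = GeneRecord("g", "1", 1_000_000, 1_050_000)
        got = snps_in_window(gene, toy_map, 100_000)
        # 900_000 and 1_150_000 are exactly on the boundary: included
        assert set(got.snp_ids) == {"s1", "s2", "s3", "s4"}

    def test_zero_window_is_the_gene_body(self, toy_map):
        gene = GeneRecord("g", "1", 1_000_000, 1_050_000)
        got = snps_in_window(gene, toy_map, 0)
        assert set(got.snp_ids) == {"s2", "s3"}

    def test_ghr_window_interval(self):
        ghr = GeneRecord("GHR", "20", 31790736, 32299996)
        assert ghr.window(100_000) == (31_690_736, 32_399_996)

    def test_window_truncates_at_position_one(self):
        gene = GeneRecord("g", "1", 50, 80)
        assert gene.window(100_000) == (1, 100_080)

    def test_absent_chromosome_warns_and_returns_empty(self, toy_map, caplog):
        gene = GeneRecord("g", "99", 10, 20)
        with caplog.at_level("WARNING"):
            got = snps_in_window(gene, toy_map, 100)
        assert got.n_snps == 0
        assert "99" in caplog.text

    @given(window=st.integers(min_value=0, max_value=500_000))
    @settings(max_examples=30, deadline=None)
    def test_window_scan_matches_brute_force(self, window):
        rng = np.random.default_rng(99)
        pos = np.sort(rng.choice(2_000_000, size=300, replace=False)) + 1
        smap = SnpMap([f"s{i}" for i in range(300)], ["7"] * 300, pos)
        gene = GeneRecord("g", "7", 800_000, 900_000)
        lo, hi = max(1, 800_000 - window), 900_000 + window
        expected = {f"s{i}" for i, p in enumerate(pos) if lo <= p <= hi}
        assert set(snps_in_window(gene, smap, window).snp_ids) == expected


class TestPathwaySnpSets:
    def _map(self):
        pos = list(range(1_000, 13_000, 1_000))
        return SnpMap([f"s{i}" for i in range(len(pos))], ["1"] * len(pos), pos)

    def test_disjoint_windows_union(self):
        smap = self._map()
        genes = [GeneRecord("a", "1", 1_000, 5_000), GeneRecord("b", "1", 6_000, 12_000)]
        ss = pathway_snp_set(Pathway("p", ("a", "b")), genes, smap, 0)
        assert ss.n_snps == 5 + 7

    def test_overlapping_windows_deduplicate(self):
        smap = self._map()
        genes = [GeneRecord("a", "1", 1_000, 5_000), GeneRecord("b", "1", 3_000, 9_000)]
        ss = pathway_snp_set(Pathway("p", ("a", "b")), genes, smap, 0)
        assert ss.n_snps == 9  # 5 + 7 - 3 shared

    def test_single_gene_equals_window_scan(self):
        smap = self._map()
        gene = GeneRecord("a", "1", 2_000, 7_000)
        ss = pathway_snp_set(Pathway("p", ("a",)), [gene], smap, 500)
        assert set(ss.snp_ids) == set(snps_in_window(gene, smap, 500).snp_ids)

    def test_gene_order_does_not_matter(self):
        smap = self._map()
        genes = [GeneRecord("a", "1", 1_000, 5_000), GeneRecord("b", "1", 3_000, 9_000)]
        s1 = pathway_snp_set(Pathway("p", ("a", "b")), genes, smap, 100)
        s2 = pathway_snp_set(Pathway("p", ("b", "a")), genes, smap, 100)
        assert s1.snp_ids == s2.snp_ids

    def test_missing_symbols_are_listed(self):
        smap = self._map()
        with pytest.raises(AnnotationError, match="GHOST"):
            pathway_snp_set(Pathway("p", ("GHOST",)), [], smap, 0)

    def test_empty_pathway_is_an_error(self):
        with pytest.raises(AnnotationError, match="empty"):
            pathway_snp_set(Pathway("p", ()), [], self._map(), 0)


class TestDiagnostics:
    def test_gap_between_separated_genes(self):
        genes = [GeneRecord("a", "1", 100, 200), GeneRecord("b", "1", 500, 600)]
        assert gene_pair_distances(genes) == [("1", 299)]

    def test_overlapping_genes_have_zero_distance(self):
        genes = [GeneRecord("a", "1", 100, 400), GeneRecord("b", "1", 300, 600)]
        assert gene_pair_distances(genes) == [("1", 0)]

    def test_cross_chromosome_pairs_are_omitted(self):
        genes = [GeneRecord("a", "1", 100, 200), GeneRecord("b", "2", 500, 600)]
        assert gene_pair_distances(genes) == []

    def test_mammary_pathway_minus_chr20(self):
        genes = packaged_gene_table("mammary_development")
        kept = exclude_chromosome(genes, "20")
        removed = {g.symbol for g in genes} - {g.symbol for g in kept}
        assert removed == {"FGF10", "MSX2", "PRLR", "GHR"}
        assert len(kept) == 60

    def test_involution_pathway_minus_chr14(self):
        genes = packaged_gene_table("involution")
        kept = exclude_chromosome(genes, "14")
        removed = {g.symbol for g in genes} - {g.symbol for g in kept}
        assert removed == {"CEBPD", "MYC", "PTK2"}

    def test_excluding_an_absent_chromosome_changes_nothing(self):
        genes = packaged_gene_table("involution")
        assert exclude_chromosome(genes, "unplaced") == genes

    def test_snpset_exclusion_commutes_with_set_construction(self, tiny_sim):
        pw, genes, smap = tiny_sim.pathways[0], tiny_sim.genes, tiny_sim.snps
        full = pathway_snp_set(pw, genes, smap, 50_000)
        via_snps = exclude_chromosome(full, "2", snps=smap)
        genes2 = exclude_chromosome(genes, "2")
        kept_genes = tuple(g for g in pw.genes if any(r.symbol == g for r in genes2))
        via_genes = pathway_snp_set(Pathway(pw.name, kept_genes), genes2, smap, 50_000)
        # gene-level exclusion can only LOSE window SNPs that chr-2 genes
        # contributed; SNP-level exclusion of the same set keeps the rest
        assert set(via_genes.snp_ids) <= set(via_snps.snp_ids)
        assert all(smap.chrom[smap.index_of(s)] != "2" for s in via_snps.snp_ids)


class TestPathwayOverlap:
    def test_lactation_pathways_triple_intersection(self):
        regions = pathway_overlap(packaged_pathways())
        triple = regions[
            frozenset(
                ["mammary_development", "prolactin_signalling", "involution"]
            )
        ]
        assert sorted(triple) == ["SOCS3", "STAT5A", "STAT5B"]

    def test_regions_partition_the_union(self):
        pws = packaged_pathways()
        regions = pathway_overlap(pws)
        total = sum(len(v) for v in regions.values())
        assert total == len({g for p in pws for g in p.genes})

    def test_disjoint_pathways(self):
        regions = pathway_overlap(
            [Pathway("a", ("g1", "g2")), Pathway("b", ("g3",))]
        )
        assert frozenset(["a", "b"]) not in regions

    def test_identical_pathways(self):
        regions = pathway_overlap(
            [Pathway("a", ("g1", "g2")), Pathway("b", ("g1", "g2"))]
        )
        assert regions == {frozenset(["a", "b"]): ["g1", "g2"]}

    def test_universe_is_consistent_across_tables(self):
        assert len(packaged_gene_universe()) == 105


class TestValidation:
    def test_gene_with_reversed_interval_rejected(self):
        with pytest.raises(AnnotationError):
            GeneRecord("g", "1", 10, 5)

    def test_pathway_duplicate_genes_rejected(self):
        with pytest.raises(AnnotationError):
            Pathway("p", ("a", "a"))

    def test_snpset_duplicates_rejected(self):
        with pytest.raises(AnnotationError):
            SnpSet("p", ("s1", "s1"))

    def test_snpmap_duplicate_ids_rejected(self):
        with pytest.raises(AnnotationError):
            SnpMap(["s1", "s1"], ["1", "1"], [1, 2])
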