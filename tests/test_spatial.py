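"""Spatial clustering statistics: permutation null, sliding windows,
and subtelomere tests."""

import numpy as np
import pandas as pd
import pytest

from gbgcscan import spatial as sp


def _toy_layout(n=5, spacing=1_000_000, chrom="chr1", length=10_000_000):
    genes = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n)],
            "chromosome": chrom,
            "start": [i * spacing for i in range(n)],
            "end": [i * spacing + 1000 for i in range(n)],
        }
    )
    return sp.GenomeLayout(genes=genes, chromosome_lengths={chrom: length})


class TestPermutationClustering:
    def test_exhaustive_island_p_on_toy_layout(self):
        """Five equally spaced genes, two adjacent outliers: 4 of the 10
        possible placements are adjacent, so the exact island p is 0.4."""
        layout = _toy_layout()
        res = sp.permutation_clustering(
            layout, {"g1", "g2"}, [f"g{i}" for i in range(5)]
        )
        isl = res["island_genes"]
        assert isl.exact
        assert isl.observed == 2
        assert isl.p_value == pytest.approx(0.4)

    def test_monte_carlo_matches_exhaustive(self):
        layout = _toy_layout()
        res = sp.permutation_clustering(
            layout, {"g1", "g2"}, [f"g{i}" for i in range(5)],
            n_permutations=10_000, seed=5, exhaustive_limit=0,
        )
        isl = res["island_genes"]
        assert not isl.exact
        se = np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(isl.p_value - 0.4) < 2 * se + 2 / 10_001

    def test_all_genes_outliers_degenerate(self):
        layout = _toy_layout()
        res = sp.permutation_clustering(
            layout, {f"g{i}" for i in range(5)}, [f"g{i}" for i in range(5)]
        )
        assert res["island_genes"].p_value == 1.0

    def test_fewer_than_two_outliers_distance_undefined(self):
        layout = _toy_layout()
        res = sp.permutation_clustering(
            layout, {"g1"}, [f"g{i}" for i in range(5)],
            n_permutations=100, seed=1, exhaustive_limit=0,
        )
        assert np.isnan(res["mean_distance"].observed)
        assert res["mean_distance"].p_value == 1.0

    def test_invariant_to_gene_relabeling(self):
        layout = _toy_layout()
        res1 = sp.permutation_clustering(
            layout, {"g1", "g2"}, [f"g{i}" for i in range(5)]
        )
        renamed = layout.genes.copy()
        renamed["gene"] = [f"x{9 - i}" for i in range(5)]
        layout2 = sp.GenomeLayout(genes=renamed,
                                  chromosome_lengths=layout.chromosome_lengths)
        res2 = sp.permutation_clustering(
            layout2, {"x8", "x7"}, [f"x{9 - i}" for i in range(5)]
        )
        assert res1["island_genes"].p_value == res2["island_genes"].p_value
        assert res1["mean_distance"].p_value == res2["mean_distance"].p_value

    def test_outliers_must_be_in_universe(self):
        layout = _toy_layout()
        with pytest.raises(ValueError):
            sp.permutation_clustering(layout, {"nope"}, ["g0", "g1"])

    def test_distance_excludes_cross_chromosome_pairs(self):
        genes = pd.DataFrame(
            {
                "gene": ["a1", "a2", "b1", "b2"],
                "chromosome": ["chr1", "chr1", "chr2", "chr2"],
                "start": [0, 2_000_000, 0, 8_000_000],
                "end": [1000, 2_001_000, 1000, 8_001_000],
            }
        )
        layout = sp.GenomeLayout(genes=genes,
                                 chromosome_lengths={"chr1": 10_000_000,
                                                     "chr2": 10_000_000})
        res = sp.permutation_clustering(
            layout, {"a1", "a2", "b1", "b2"},
            ["a1", "a2", "b1", "b2"],
        )
        # consecutive same-chromosome distances: 2 Mb and 8 Mb
        assert res["mean_distance"].observed == pytest.approx(5_000_000)


class TestSlidingWindowScan:
    def test_flat_values_give_no_regions(self):
        layout = _toy_layout(n=10, spacing=200_000, length=3_000_000)
        values = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        assert sp.sliding_window_scan(layout, values) == []

    def test_dense_high_cluster_yields_one_region(self):
        """Six genes at 0.1-0.9 Mb with value 5 on a background of ones:
        brute-force window enumeration finds exactly one region there."""
        rows = []
        for i in range(6):
            rows.append((f"hot{i}", "chr1", int(1e5 + i * 1.6e5), int(1e5 + i * 1.6e5) + 100))
        for i in range(20):
            rows.append((f"bg{i}", "chr1", int(3e6 + i * 6e5), int(3e6 + i * 6e5) + 100))
        genes = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])
        layout = sp.GenomeLayout(genes=genes, chromosome_lengths={"chr1": 16_000_000})
        values = pd.Series(
            {g: (5.0 if g.startswith("hot") else 1.0) for g in genes.gene}
        )
        regions = sp.sliding_window_scan(layout, values)
        assert len(regions) == 1
        r = regions[0]
        assert r.chromosome == "chr1" and r.start == 0 and r.n_genes == 6

    def test_translation_consistency(self):
        """Shifting all coordinates by one full step shifts the detected
        region by the same amount."""
        rows = [(f"hot{i}", "chr1", int(1e6 + i * 1.5e5), int(1e6 + i * 1.5e5) + 100)
                for i in range(6)]
        genes = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])
        step = 250_000
        layout1 = sp.GenomeLayout(genes=genes, chromosome_lengths={"chr1": 20_000_000})
        shifted = genes.assign(start=genes.start + step, end=genes.end + step)
        layout2 = sp.GenomeLayout(genes=shifted, chromosome_lengths={"chr1": 20_000_000})
        values = pd.Series(5.0, index=genes.gene)
        r1 = sp.sliding_window_scan(layout1, values)
        r2 = sp.sliding_window_scan(layout2, values)
        assert len(r1) == len(r2) == 1
        assert r2[0].start - r1[0].start == pytest.approx(step)

    def test_median_statistic_option(self):
        rows = [(f"g{i}", "chr1", int(1e5 + i * 1.5e5), int(1e5 + i * 1.5e5) + 100)
                for i in range(5)]
        genes = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])
        layout = sp.GenomeLayout(genes=genes, chromosome_lengths={"chr1": 5_000_000})
        # one huge value inflates the mean but not the median
        values = pd.Series([50.0, 1.0, 1.0, 1.0, 1.0], index=genes.gene)
        assert len(sp.sliding_window_scan(layout, values, statistic="mean")) == 1
        assert sp.sliding_window_scan(layout, values, statistic="median") == []


class TestSubtelomeres:
    def test_midpoint_flags(self):
        genes = pd.DataFrame(
            {
                "gene": ["near", "far"],
                "chromosome": ["chr1", "chr1"],
                "start": [2_999_500, 49_999_500],
                "end": [3_000_500, 50_000_500],
            }
        )
        layout = sp.GenomeLayout(genes=genes, chromosome_lengths={"chr1": 100_000_000})
        res = sp.subtelomere_enrichment(layout, set(), ["near", "far"])
        assert res["subtelomeric_flags"]["near"]
        assert not res["subtelomeric_flags"]["far"]

    def test_chi2_matches_textbook_formula(self):
        """2x2 chi-squared without continuity correction on the table
        [[10, 90], [5, 895]] equals sum((O-E)^2/E)."""
        table = np.array([[10, 90], [5, 895]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = (((table - expected) ** 2) / expected).sum()
        genes = []
        flags = set()
        k = 0
        # build a layout reproducing that table: rows outlier yes/no,
        # columns subtelomeric yes/no on a 100 Mb chromosome
        for (n, outlier, sub) in ((10, True, True), (90, True, False),
                                  (5, False, True), (895, False, False)):
            for _ in range(n):
                pos = 1_000_000 if sub else 50_000_000
                genes.append((f"g{k}", "chr1", pos, pos + 100))
                if outlier:
                    flags.add(f"g{k}")
                k += 1
        frame = pd.DataFrame(genes, columns=["gene", "chromosome", "start", "end"])
        layout = sp.GenomeLayout(genes=frame, chromosome_lengths={"chr1": 100_000_000})
        res = sp.subtelomere_enrichment(layout, flags, list(frame.gene))
        assert np.array_equal(res["table"], table)
        assert res["chi2"] == pytest.approx(chi2_hand)

    def test_short_chromosome_warned(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chromosome": ["tiny"], "start": [100], "end": [200]}
        )
        layout = sp.GenomeLayout(genes=genes, chromosome_lengths={"tiny": 4_000_000})
        res = sp.subtelomere_enrichment(layout, set(), ["g"])
        assert res["warnings"] == ["tiny"]
        assert res["subtelomeric_flags"]["g"]


class TestGeneticMapSubtelomeres:
    def test_default_margin_is_derived_from_rate(self):
        gm = pd.DataFrame({"gene": ["g"], "linkage_group": ["lg1"], "cM": [10.0]})
        res = sp.genetic_map_subtelomeres(gm)
        assert res["margin_cm"] == pytest.approx(2.85)

    def test_end_and_middle_flags(self):
        gm = pd.DataFrame(
            {
                "gene": ["start", "middle", "end"],
                "linkage_group": ["lg1"] * 3,
                "cM": [0.0, 30.0, 60.0],
            }
        )
        res = sp.genetic_map_subtelomeres(gm)
        assert res["subtelomeric_flags"]["start"]
        assert not res["subtelomeric_flags"]["middle"]
        assert res["subtelomeric_flags"]["end"]

    def test_unmapped_genes_reported(self):
        gm = pd.DataFrame(
            {"gene": ["g1"], "linkage_group": ["lg1"], "cM": [5.0]}
        )
        res = sp.genetic_map_subtelomeres(gm, universe=["g1", "g2"])
        assert res["unmapped"] == ["g2"]
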