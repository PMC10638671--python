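"""Peak-gene geometry, contingency tests, group comparisons, density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cistrans_atac as ct
from cistrans_atac.association import (
    category_enrichment,
    chi2_independence,
    gene_window_counts,
    group_compare,
    nearest_gene,
    peak_density,
    peaks_in_window,
    regmode_focused_test,
)
from cistrans_atac.datatypes import GeneModel, PeakInterval, link_category

from oracles import chi2_textbook, fisher_exact_enumeration, nearest_gene_scan, window_scan


def _peak(center, pid, chrom="chr1", width=100):
    return PeakInterval(chrom, center - width // 2, center + width // 2, pid)


def _gene(tls, gid, chrom="chr1", **kw):
    return GeneModel(gid, chrom, tls, "+", **kw)


class TestNearestGene:
    def test_single_gene(self):
        links = nearest_gene([_peak(1500, "p1")], [_gene(1000, "gA")])
        assert links.loc["p1", "gene_id"] == "gA"
        assert links.loc["p1", "distance"] == 500

    def test_boundary_distance_is_proximal(self):
        links = nearest_gene([_peak(1500, "p1")], [_gene(1000, "gA"), _gene(5000, "gB")])
        assert links.loc["p1", "gene_id"] == "gA"
        assert links.loc["p1", "category"] == "proximal"

    def test_equidistant_tie_lexicographic(self):
        links = nearest_gene([_peak(2000, "p1")], [_gene(1500, "gB"), _gene(2500, "gA")])
        assert links.loc["p1", "gene_id"] == "gA"

    def test_chromosome_without_genes_logged_absent(self, caplog):
        links = nearest_gene([_peak(100, "p1", chrom="chrX")], [_gene(1000, "gA")])
        assert pd.isna(links.loc["p1", "gene_id"])

    def test_matches_brute_force(self, rng):
        for _ in range(40):
            peaks = [
                _peak(int(c), f"p{i}", chrom=str(rng.choice(["chr1", "chr2"])), width=2)
                for i, c in enumerate(rng.integers(100, 100_000, size=rng.integers(1, 60)))
            ]
            genes = [
                _gene(int(t), f"g{i}", chrom=str(rng.choice(["chr1", "chr2"])))
                for i, t in enumerate(rng.integers(0, 100_000, size=rng.integers(1, 40)))
            ]
            links = nearest_gene(peaks, genes)
            expect = nearest_gene_scan(peaks, genes)
            for pid, best in expect.items():
                if best is None:
                    assert pd.isna(links.loc[pid, "gene_id"])
                else:
                    assert links.loc[pid, "gene_id"] == best[0]
                    assert links.loc[pid, "distance"] == best[1]

    def test_category_partition_exhaustive(self, rng):
        for d in rng.integers(0, 60_000, size=200):
            assert link_category(d) in ("proximal", "distal", "beyond")
        assert link_category(500) == "proximal"
        assert link_category(501) == "distal"
        assert link_category(25_000) == "distal"
        assert link_category(25_001) == "beyond"


class TestWindowQueries:
    def test_inclusive_boundary(self):
        gene = _gene(100_000, "g")
        assert peaks_in_window(gene, [_peak(125_000, "p1")], 25_000) == ["p1"]

    def test_empty_chromosome(self):
        gene = _gene(100_000, "g", chrom="chr9")
        assert peaks_in_window(gene, [_peak(100_000, "p1")], 25_000) == []

    def test_four_of_five(self):
        gene = _gene(0, "g")
        peaks = [
            _peak(100, "a"), _peak(1000, "b"), _peak(10_000, "c"),
            _peak(25_000, "d"), _peak(30_000, "e"),
        ]
        assert sorted(peaks_in_window(gene, peaks, 25_000)) == ["a", "b", "c", "d"]

    def test_matches_brute_force(self, rng):
        for _ in range(40):
            peaks = [
                _peak(int(c), f"p{i}", width=2)
                for i, c in enumerate(rng.integers(0, 200_000, size=50))
            ]
            gene = _gene(int(rng.integers(0, 200_000)), "g")
            w = int(rng.integers(1, 50_000))
            assert sorted(peaks_in_window(gene, peaks, w)) == window_scan(gene, peaks, w)

    def test_gene_window_counts_agree_with_query(self, rng):
        peaks = [
            _peak(int(c), f"p{i}", width=2)
            for i, c in enumerate(rng.integers(0, 500_000, size=200))
        ]
        genes = [_gene(int(t), f"g{i}") for i, t in enumerate(rng.integers(0, 500_000, size=30))]
        counts = gene_window_counts(genes, peaks, 25_000)
        for g in genes:
            assert counts.loc[g.gene_id, "n_peaks"] == len(peaks_in_window(g, peaks, 25_000))


class TestChi2:
    def test_proportional_table_zero_statistic(self):
        res = chi2_independence([[10, 20], [20, 40]], continuity=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.residuals, 0.0)

    def test_worked_continuity_example(self):
        res = chi2_independence([[30, 10], [20, 40]], continuity=True)
        assert res.statistic == pytest.approx(15.0417, abs=1e-4)
        assert res.df == 1

    def test_worked_residual(self):
        res = chi2_independence([[30, 10], [20, 40]])
        assert res.residuals[0, 0] == pytest.approx((30 - 20) / np.sqrt(20), abs=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_independence([[0, 0], [5, 10]])

    def test_matches_textbook_formula_on_random_tables(self, rng):
        for _ in range(1000):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 80, size=(r, c))
            res = chi2_independence(table, continuity=False)
            stat, resid = chi2_textbook(table)
            assert res.statistic == pytest.approx(stat, abs=1e-9)
            assert np.allclose(res.residuals, resid, atol=1e-9)
            assert (res.residuals**2).sum() == pytest.approx(res.statistic, abs=1e-9)


class TestFisher:
    def test_balanced_table(self):
        res = category_enrichment(
            np.repeat([True, False], 10), np.tile(np.repeat([True, False], 5), 2)
        )
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_enumeration_oracle_single_table(self):
        # [[8,2],[2,8]]
        cat = np.repeat([True, False], 10)
        ind = np.concatenate([np.repeat([True, False], [8, 2]), np.repeat([True, False], [2, 8])])
        res = category_enrichment(cat, ind)
        assert res.p == pytest.approx(fisher_exact_enumeration([[8, 2], [2, 8]]), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            category_enrichment(np.array([True, True]), np.array([True, False]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=15), min_size=4, max_size=4))
    def test_matches_full_enumeration_small_tables(self, cells):
        a, b, c, d = cells
        cat = np.repeat([True, False], [a + b, c + d])
        ind = np.concatenate(
            [np.repeat([True, False], [a, b]), np.repeat([True, False], [c, d])]
        )
        res = category_enrichment(cat, ind)
        assert res.p == pytest.approx(fisher_exact_enumeration([[a, b], [c, d]]), abs=1e-9)


class TestGroupCompare:
    def test_identical_groups(self):
        r = group_compare({"a": [1.0, 2, 3], "b": [1.0, 2, 3]}, "welch_t")
        assert r["statistic"] == 0.0 and r["p"] == 1.0
        r = group_compare({"a": [1.0, 2, 3], "b": [1.0, 2, 3]}, "ks")
        assert r["statistic"] == 0.0

    def test_disjoint_supports_ks_one(self):
        r = group_compare({"a": [1.0, 2, 3], "b": [11.0, 12, 13]}, "ks")
        assert r["statistic"] == 1.0

    def test_anova_equal_means(self, rng):
        base = rng.normal(size=30)
        groups = {k: base + rng.normal(scale=1e-6, size=30) for k in "abc"}
        r = group_compare(groups, "anova_scheffe")
        assert r["statistic"] == pytest.approx(0.0, abs=0.1)
        assert not any(v["significant"] for v in r["pairwise"].values())

    def test_anova_detects_shifted_group(self, rng):
        groups = {
            "a": rng.normal(size=40),
            "b": rng.normal(size=40),
            "c": rng.normal(loc=3.0, size=40),
        }
        r = group_compare(groups, "anova_scheffe")
        assert r["p"] < 1e-6
        assert r["pairwise"][("a", "c")]["significant"]
        assert not r["pairwise"][("a", "b")]["significant"]


class TestAssociationTests:
    @staticmethod
    def _setup(odds, seed):
        truth = ct.make_truth(
            3000, {"conserved": 0.7, "cis": 0.15, "trans": 0.15}, seed=seed
        )
        genes, peaks, dist = ct.make_annotation(1200, 240_000_000, truth, seed=seed + 500)
        expr = ct.simulate_expression_table(
            genes, truth, dist, odds, seed=seed + 900, stages=["blastula"]
        )
        da = {t.peak_id: t.true_regulatory_mode != "conserved" for t in truth}
        e = expr.set_index("gene_id")
        de = e["de_status"].astype(bool).to_dict()
        modes = e["expr_mode"].to_dict()
        return truth, genes, peaks, da, de, modes

    def test_coupled_generator_detected(self):
        hits = 0
        for seed in range(10):
            truth, genes, peaks, da, de, _ = self._setup(3.0, seed)
            links = ct.nearest_gene(peaks, genes)
            r1 = ct.peaks_focused_test(links, da, de)
            r2 = ct.gene_focused_test(genes, peaks, da, de)
            hits += (r1.p < 0.05 and r1.residuals[0, 0] > 0
                     and r2.p < 0.05 and r2.residuals[0, 0] > 0)
        assert hits >= 9

    def test_independent_generator_near_null(self):
        hits = 0
        for seed in range(10):
            truth, genes, peaks, da, de, _ = self._setup(1.0, seed)
            links = ct.nearest_gene(peaks, genes)
            r1 = ct.peaks_focused_test(links, da, de)
            r2 = ct.gene_focused_test(genes, peaks, da, de)
            hits += (r1.p < 0.05) + (r2.p < 0.05)
        assert hits <= 2

    def test_regmode_direction(self):
        truth, genes, peaks, da, de, modes = self._setup(3.0, 42)
        r_cis, r_trans = regmode_focused_test(genes, peaks, da, modes, de)
        assert r_cis.residuals[0, 0] > 0
        assert r_trans.residuals[0, 0] < 0

    def test_all_peaks_da_zero_margin(self):
        links = nearest_gene([_peak(1000, "p1"), _peak(5000, "p2")], [_gene(900, "g")])
        with pytest.raises(ValueError, match="margin"):
            ct.peaks_focused_test(links, {"p1": True, "p2": True}, {"g": True})

    def test_no_de_genes_rejected(self):
        genes = [_gene(1000, "g")]
        with pytest.raises(ValueError, match="differentially expressed"):
            regmode_focused_test(genes, [_peak(900, "p")], {"p": True}, {"g": "cis"}, {"g": False})


class TestPeakDensity:
    def test_no_peaks_all_zero(self):
        genes = [_gene(1000, "g1"), _gene(50_000, "g2")]
        d = peak_density(genes, [])
        assert (d == 0).all()
        r = group_compare({"a": d, "b": d}, "ks")
        assert r["statistic"] == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            peak_density([], [_peak(100, "p")])

    def test_brute_force_equivalence(self, rng):
        peaks = [
            _peak(int(c), f"p{i}", width=2)
            for i, c in enumerate(rng.integers(0, 1_000_000, size=300))
        ]
        genes = [_gene(int(t), f"g{i}") for i, t in enumerate(rng.integers(0, 1_000_000, size=40))]
        d = peak_density(genes, peaks)
        for g in genes:
            brute = sum(
                1 for p in peaks if abs((p.start + p.end) // 2 - g.tls) <= 25_000
            )
            assert d[g.gene_id] == brute

    def test_elevated_density_near_grn_genes_detected(self):
        wins = 0
        for seed in range(10):
            truth = ct.make_truth(3000, {"conserved": 1.0}, seed=seed)
            genes, peaks, _ = ct.make_annotation(
                600, 100_000_000, truth, seed=seed + 40, grn_peak_weight=3.0
            )
            grn = [g for g in genes if g.is_grn]
            other = [g for g in genes if not g.is_grn]
            r = group_compare(
                {"grn": peak_density(grn, peaks), "other": peak_density(other, peaks)},
                "ks",
            )
            wins += r["p"] < 0.05
        assert wins >= 9
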