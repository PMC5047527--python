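"""Fisher designs, fold-enrichment scans, and category representation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from microase import enrichment as en
from microase.simulate import simulate_gwas_catalog


def brute_fisher_two_sided(a, b, c, d):
    """Enumerate all tables with the observed margins; sum the probability
    of tables no more likely than the observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


class TestFisherOverlap:
    def test_odds_ratio_arithmetic(self):
        universe = {f"g{i}" for i in range(100)}
        genes = sorted(universe)
        set_a = set(genes[:10])
        set_b = set(genes[:5]) | set(genes[10:15])
        res = en.fisher_overlap(set_a, set_b, universe)
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (5, 5, 5, 85)
        assert res.odds_ratio == pytest.approx(17.0)

    def test_degenerate_full_overlap(self):
        u = {"a", "b", "c"}
        res = en.fisher_overlap(u, u, u)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)
        assert math.isnan(res.odds_ratio)

    def test_exact_independence(self):
        universe = {f"g{i}" for i in range(1000)}
        genes = sorted(universe)
        set_a = set(genes[:100])
        set_b = set(genes[:10]) | set(genes[100:190])
        res = en.fisher_overlap(set_a, set_b, universe)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fold == pytest.approx(1.0)

    def test_outside_universe_dropped(self):
        res = en.fisher_overlap({"x", "a"}, {"x", "b"}, {"x", "a", "b", "c"})
        assert res.table.a == 1

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            en.fisher_overlap(set(), set(), set())

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_two_sided_p_matches_enumeration(self, a, b, c, d):
        if a + b + c + d == 0 or a + b + c + d > 40:
            return
        res = en._fisher_result(en.ContingencyTable(a, b, c, d))
        assert res.p == pytest.approx(brute_fisher_two_sided(a, b, c, d), abs=1e-9)

    def test_transpose_invariance(self):
        universe = {f"g{i}" for i in range(200)}
        genes = sorted(universe)
        sa, sb = set(genes[:30]), set(genes[20:80])
        r1 = en.fisher_overlap(sa, sb, universe)
        r2 = en.fisher_overlap(sb, sa, universe)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)
        assert r1.fold == pytest.approx(r2.fold)
        assert r1.p == pytest.approx(r2.p)


class TestGwasTraitEnrichment:
    def catalog(self):
        return pd.DataFrame({
            "gene": ["g1", "g2", "g3", "g4", "g5", "g1"],
            "trait": ["T", "T", "O", "O", "O", "O"],
            "pvalue": [1e-8] * 6,
        })

    def test_zero_overlap(self):
        res = en.gwas_trait_enrichment(
            {"g5"}, {f"g{i}" for i in range(1, 8)}, self.catalog(), "T")
        assert res.table.a == 0 and res.fold == 0.0

    def test_focal_trait_precedence(self):
        # g1 is in both T and O; it must count in the TRAIT column
        res = en.gwas_trait_enrichment(
            {"g1"}, {f"g{i}" for i in range(1, 8)}, self.catalog(), "T")
        assert res.table.a == 1 and res.table.b == 0

    def test_universe_restricted_to_catalog(self):
        res = en.gwas_trait_enrichment(
            {"g1", "g7"}, {f"g{i}" for i in range(1, 10)}, self.catalog(), "T")
        # g6..g9 absent from the catalog: restricted universe is g1..g5
        assert res.table.n == 5

    def test_unknown_trait_lists_available(self):
        with pytest.raises(ValueError, match="available"):
            en.gwas_trait_enrichment({"g1"}, {"g1"}, self.catalog(), "Z")

    def test_planted_odds_recovered(self):
        genes = [f"g{i:05d}" for i in range(15000)]
        de = set(genes[:1500])
        ors = []
        for seed in range(5):
            cat = simulate_gwas_catalog(genes, de, enrichment_odds=3.0, seed=seed)
            res = en.gwas_trait_enrichment(de, set(genes), cat, "TraitA")
            ors.append(res.odds_ratio)
        assert 2.0 <= np.mean(ors) <= 4.5


class TestThresholdScan:
    def brute_scan(self, de_set, universe, assoc, trait, grid):
        gene_p = {}
        for _, row in assoc[assoc["trait"] == trait].iterrows():
            if row["gene"] in universe:
                gene_p[row["gene"]] = min(
                    gene_p.get(row["gene"], 1.0), row["pvalue"])
        rows = []
        for c in grid:
            hit = {g for g, p in gene_p.items() if p <= 10 ** (-c)}
            if not hit:
                continue
            obs = len(hit & de_set & universe)
            expected = len(hit) * len(de_set & universe) / len(universe)
            rows.append((c, len(hit), obs, expected,
                         obs / expected if expected else 0.0))
        return rows

    def setup_instance(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(200)]
        universe = set(genes)
        de = set(rng.choice(genes, size=40, replace=False))
        rows = []
        for g in genes:
            if rng.random() < 0.5:
                rows.append((g, "T", 10.0 ** -rng.uniform(4, 12)))
        assoc = pd.DataFrame(rows, columns=["gene", "trait", "pvalue"])
        return de, universe, assoc

    def test_matches_counting_oracle(self):
        de, universe, assoc = self.setup_instance()
        grid = np.arange(4.0, 11.0, 0.7)
        scan = en.threshold_scan(de, universe, assoc, "T", grid)
        oracle = self.brute_scan(de, universe, assoc, "T", grid)
        assert len(scan) == len(oracle)
        for row, (c, size, obs, expected, fold) in zip(scan.itertuples(), oracle):
            assert row.cutoff == pytest.approx(c)
            assert row.set_size == size and row.observed == obs
            assert row.expected == pytest.approx(expected)
            assert row.fold == pytest.approx(fold)

    def test_de_equals_universe_fold_one(self):
        de, universe, assoc = self.setup_instance(1)
        scan = en.threshold_scan(universe, universe, assoc, "T",
                                 np.arange(4.0, 10.0, 1.0))
        assert np.allclose(scan["fold"], 1.0)

    def test_loosest_cutoff_agrees_with_fisher_overlap(self):
        de, universe, assoc = self.setup_instance(2)
        # a cutoff loose enough to capture every catalog entry
        scan = en.threshold_scan(de, universe, assoc, "T", np.array([1.0, 8.0]))
        trait_genes = set(assoc["gene"])
        res = en.fisher_overlap(de, trait_genes, universe)
        assert scan.iloc[0]["fold"] == pytest.approx(res.fold)

    def test_set_size_non_increasing_and_grid_validation(self):
        de, universe, assoc = self.setup_instance(3)
        scan = en.threshold_scan(de, universe, assoc, "T")
        assert np.all(np.diff(scan["set_size"]) <= 0)
        with pytest.raises(ValueError):
            en.threshold_scan(de, universe, assoc, "T", np.array([]))
        with pytest.raises(ValueError):
            en.threshold_scan(de, universe, assoc, "T", np.array([5.0, 4.0]))

    def test_planted_signal_peaks_at_strict_cutoffs(self):
        """Stronger associations inside the DE overlap: max fold beyond the
        background association range in most seeds."""
        genes = [f"g{i:05d}" for i in range(4000)]
        de = set(genes[:400])
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cat = simulate_gwas_catalog(genes, de, enrichment_odds=3.0, seed=seed)
            scan = en.threshold_scan(de, set(genes), cat, "TraitA")
            if scan.attrs["max_fold_cutoff"] >= 8.0:
                wins += 1
        assert wins >= 0.8 * n_seeds


class TestSetRepresentation:
    def test_query_equals_category(self):
        bg = {f"g{i}" for i in range(100)}
        genes = sorted(bg)
        query = set(genes[:10])
        cats = {"hit": query, "miss": set(genes[50:90])}
        out = en.set_representation(query, cats, bg).set_index("category")
        assert out.loc["hit", "enrichment"] == pytest.approx(10.0)
        assert out.loc["hit", "p_over"] < 1e-10
        assert out.loc["miss", "observed"] == 0

    def test_expected_band_boundaries(self):
        bg = {f"g{i}" for i in range(2000)}
        genes = sorted(bg)
        query = set(genes[:1000])  # expected = category size * 0.5
        cats = {"small": set(genes[:19]), "lo": set(genes[:20]),
                "hi": set(genes[:1000]), "big": set(genes[:1002])}
        out = en.set_representation(query, cats, bg).set_index("category")
        assert not out.loc["small", "in_band"]  # expected 9.5 < 10
        assert out.loc["lo", "in_band"]         # expected 10.0: closed band
        assert out.loc["hi", "in_band"]         # expected 500.0: closed band
        assert not out.loc["big", "in_band"]    # expected 501.0 > 500

    def test_null_query_mostly_unflagged(self):
        rng = np.random.default_rng(4)
        bg = {f"g{i}" for i in range(2000)}
        genes = np.array(sorted(bg))
        query = set(rng.choice(genes, 200, replace=False))
        cats = {f"c{j}": set(rng.choice(genes, 100, replace=False))
                for j in range(40)}
        out = en.set_representation(query, cats, bg)
        assert out["significant"].mean() <= 0.1
        # raw two-sided p-values roughly uniform: about 5% below 0.05
        assert (out["p"] < 0.05).mean() <= 0.2

    def test_category_outside_background_dropped(self):
        out = en.set_representation({"a"}, {"x": {"zz"}}, {"a", "b"})
        assert len(out) == 0
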