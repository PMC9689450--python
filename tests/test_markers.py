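import math

import numpy as np
import pandas as pd
import pytest

from oracles import hwe_exact_enumeration, nei_identity_distance, wc_theta_direct

from meliapop.markers import (GenotypeTable, aggregate_diversity,
                              allele_frequencies, diversity_stats, gst,
                              hwe_exact_mc, hwe_tests, multilocus_theta,
                              nei_distance, pairwise_fst, read_genotypes)


def make_gt(pop_alleles, loci=None):
    """Build a GenotypeTable from {pop: list of per-individual locus pairs}."""
    individuals, populations, rows = [], [], []
    for pop, genos in pop_alleles.items():
        for k, g in enumerate(genos):
            individuals.append(f"{pop}_{k}")
            populations.append(pop)
            rows.append(g)
    arr = np.array(rows)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    loci = loci or [f"L{i+1}" for i in range(arr.shape[1])]
    return GenotypeTable(individuals, np.array(populations), loci, arr)


# ---------------------------------------------------------------------- I/O

class TestReadGenotypes:
    def test_genalex_round_trip(self, tmp_path, island_genotypes):
        gt, _ = island_genotypes
        path = tmp_path / "geno.csv"
        gt.write_genalex(path)
        back = read_genotypes(path, dialect="genalex")
        assert back.loci == gt.loci
        assert back.individuals == gt.individuals
        np.testing.assert_array_equal(back.alleles, gt.alleles)

    def test_two_individuals_one_locus(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text("1,2,1\n2\nind,pop,LocA,\na,P1,180,182\nb,P1,180,180\n")
        gt = read_genotypes(path)
        assert gt.loci == ["LocA"]
        assert len(gt.individuals) == 2
        div = diversity_stats(gt)
        assert div.per_locus["na"].iloc[0] == 2

    def test_missing_marked_and_excluded(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("1,3,1\n3\nind,pop,LocA,\na,P1,1,2\nb,P1,0,0\nc,P1,1,1\n")
        gt = read_genotypes(path)
        freqs = allele_frequencies(gt)
        assert freqs["n"].max() == 2  # the (0,0) row contributes nothing

    def test_header_count_mismatch_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("3,1,1\n1\nind,pop,A,,B,,C,,D,\n"
                        "a,P1,1,1,1,1,1,1,1,1\n")
        with pytest.raises(ValueError, match="allele columns"):
            read_genotypes(path)

    def test_duplicate_individual_errors(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("1,2,1\n2\nind,pop,A,\nx,P1,1,1\nx,P1,1,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genotypes(path)

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_genotypes(tmp_path / "nope.csv", dialect="structure")

    def test_long_dialect_round_trip(self, tmp_path, tiny_gt):
        path = tmp_path / "long.csv"
        tiny_gt.write_long(path)
        back = read_genotypes(path, dialect="long")
        np.testing.assert_array_equal(back.alleles, tiny_gt.alleles)


# -------------------------------------------------------------- frequencies

class TestAlleleFrequencies:
    @pytest.mark.parametrize("genos,expected", [
        ([(1, 2)] * 4, {1: 0.5, 2: 0.5}),
        ([(1, 1)] * 3, {1: 1.0}),
        ([(1, 1), (1, 2), (2, 2)], {1: 0.5, 2: 0.5}),
    ])
    def test_counts(self, genos, expected):
        gt = make_gt({"P": genos})
        freqs = allele_frequencies(gt)
        got = dict(zip(freqs["allele"], freqs["frequency"]))
        assert got == pytest.approx(expected)

    def test_empty_cell_flagged_not_zero(self):
        gt = make_gt({"P": [(0, 0), (0, 0)], "Q": [(1, 2), (1, 1)]})
        freqs = allele_frequencies(gt)
        empty = freqs[(freqs["population"] == "P")]
        assert len(empty) == 1 and empty["n"].iloc[0] == 0
        assert np.isnan(empty["frequency"].iloc[0])


# ---------------------------------------------------------------- diversity

class TestDiversity:
    def test_biallelic_half_formulas(self):
        # p = (0.5, 0.5), n = 15: direct evaluation of every index
        genos = [(1, 2)] * 7 + [(1, 1)] * 4 + [(2, 2)] * 4
        gt = make_gt({"P": genos})
        row = diversity_stats(gt).per_locus.iloc[0]
        assert row["ne"] == pytest.approx(2.0)
        assert row["h"] == pytest.approx(0.5)
        assert row["he"] == pytest.approx(30 / 29 * 0.5)
        assert row["i"] == pytest.approx(math.log(2))
        assert row["pic"] == pytest.approx(0.375)

    def test_monomorphic_zeros(self):
        gt = make_gt({"P": [(3, 3)] * 10})
        row = diversity_stats(gt).per_locus.iloc[0]
        assert row["na"] == 1
        assert row["ne"] == pytest.approx(1.0)
        for stat in ("h", "he", "i", "pic"):
            assert row[stat] == pytest.approx(0.0)

    def test_fis_zero_when_ho_equals_h(self):
        # Ho = 0.5 = h exactly at p = (0.5, 0.5) with half heterozygotes
        genos = [(1, 2)] * 4 + [(1, 1)] * 2 + [(2, 2)] * 2
        gt = make_gt({"P": genos})
        row = diversity_stats(gt).per_locus.iloc[0]
        assert row["fis"] == pytest.approx(0.0)

    def test_pic_h_he_ordering_invariant(self, island_genotypes):
        gt, _ = island_genotypes
        per_locus = diversity_stats(gt).per_locus
        poly = per_locus[per_locus["na"] > 1]
        assert (poly["pic"] <= poly["h"] + 1e-12).all()
        assert (poly["h"] <= poly["he"] + 1e-12).all()
        ratio = poly["he"] / poly["h"]
        expected = 2 * poly["n"] / (2 * poly["n"] - 1)
        assert np.allclose(ratio, expected)

    def test_aggregate_single_population(self):
        df = pd.DataFrame({"population": ["A"], "na": [5.0], "he": [0.8]})
        agg = aggregate_diversity(df)
        assert agg.loc["na", "mean"] == 5.0
        assert agg.loc["na", "sd"] == 0.0

    def test_aggregate_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_diversity(pd.DataFrame())


# --------------------------------------------------------------------- HWE

class TestHWE:
    def test_exact_mc_matches_enumeration_tiny(self):
        # AA=1, Aa=2, aa=1: every pairing equally extreme -> exact p = 1
        pairs = np.array([[1, 1], [1, 2], [1, 2], [2, 2]])
        oracle = hwe_exact_enumeration(pairs)
        assert oracle == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        p = hwe_exact_mc(pairs, 2000, rng)
        assert p == pytest.approx(oracle, abs=0.02)

    def test_exact_mc_matches_enumeration_skewed(self):
        # excess homozygotes: enumeration gives a small exact p
        pairs = np.array([[1, 1], [1, 1], [1, 1], [2, 2], [2, 2], [2, 2]])
        oracle = hwe_exact_enumeration(pairs)
        rng = np.random.default_rng(1)
        p = hwe_exact_mc(pairs, 5000, rng)
        assert p == pytest.approx(oracle, abs=3 * math.sqrt(oracle / 5000) + 0.01)

    def test_bonferroni_threshold_counts_cells(self, island_genotypes):
        gt, _ = island_genotypes
        df = hwe_tests(gt, method="chi2")
        assert df.attrs["n_tests"] == len(gt.population_labels) * len(gt.loci)
        assert df.attrs["bonferroni_threshold"] == pytest.approx(
            0.05 / df.attrs["n_tests"])

    def test_monomorphic_cell_not_applicable(self):
        gt = make_gt({"P": [(1, 1)] * 5, "Q": [(1, 2)] * 5})
        df = hwe_tests(gt, method="chi2")
        row = df[(df["population"] == "P")].iloc[0]
        assert not row["applicable"] and not row["reject"]

    def test_exact_mc_requires_enough_shuffles(self, tiny_gt):
        with pytest.raises(ValueError, match="n_mc"):
            hwe_tests(tiny_gt, method="exact_mc", n_mc=10)

    def test_calibration_under_hwe(self):
        """Rejection rate of the exact test is ~alpha on HWE data."""
        rng = np.random.default_rng(42)
        alpha, n_cells, rejections, n_mc = 0.05, 150, 0, 1000
        p_vec = np.full(6, 1 / 6)
        for _ in range(n_cells):
            pairs = rng.choice(6, size=(15, 2), p=p_vec) + 1
            p = hwe_exact_mc(pairs, n_mc, rng)
            rejections += p < alpha
        rate = rejections / n_cells
        assert 0.0 <= rate <= 0.10  # exact tests are conservative


# ----------------------------------------------------------- differentiation

class TestGst:
    def test_fixed_differences_give_one(self):
        gt = make_gt({"P": [(1, 1)] * 8, "Q": [(2, 2)] * 8})
        assert gst(gt).multilocus_gst == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        genos = [(1, 2)] * 4 + [(1, 1)] * 2 + [(2, 2)] * 2
        gt = make_gt({"P": genos, "Q": genos})
        assert abs(gst(gt).multilocus_gst) < 0.05

    def test_hand_computed_nei_chesser_value(self):
        # 2 pops, 1 locus: P has 3x(1,1)+1x(1,2); Q has 2x(2,2)+2x(1,2)
        gt = make_gt({"P": [(1, 1), (1, 1), (1, 1), (1, 2)],
                      "Q": [(2, 2), (2, 2), (1, 2), (1, 2)]})
        # by hand: n~=4, p_P=(7/8,1/8), p_Q=(1/4,3/4), Ho=(0.25+0.5)/2=0.375
        # mean sum p^2 = ((49+1)/64 + (1+9)/16)/2 = (50/64 + 40/64)/2 = 45/64
        hs = 4 / 3 * (1 - 45 / 64 - 0.375 / 8)
        pbar = np.array([(7 / 8 + 1 / 4) / 2, (1 / 8 + 3 / 4) / 2])
        ht = 1 - (pbar ** 2).sum() + hs / 8 - 0.375 / 16
        expected = (ht - hs) / ht
        assert gst(gt).multilocus_gst == pytest.approx(expected, rel=1e-12)

    def test_locus_order_and_duplication_invariance(self, island_genotypes):
        gt, _ = island_genotypes
        base = gst(gt).multilocus_gst
        rev = gst(gt.subset_loci(range(len(gt.loci) - 1, -1, -1))).multilocus_gst
        dup = gst(gt.subset_loci(list(range(len(gt.loci))) * 2)).multilocus_gst
        assert rev == pytest.approx(base, rel=1e-12)
        assert dup == pytest.approx(base, rel=1e-12)

    def test_monomorphic_locus_excluded_with_record(self):
        gt = make_gt({"P": [[(1, 2), (5, 5)]] * 4, "Q": [[(1, 1), (5, 5)]] * 4},
                     loci=["A", "B"])
        res = gst(gt)
        assert "B" in res.excluded_loci
        assert np.isfinite(res.multilocus_gst)


class TestPairwiseFst:
    def test_duplicated_population_theta_nonpositive(self, island_genotypes):
        gt, _ = island_genotypes
        sub = gt.subset_populations(gt.population_labels[:1])
        dup = GenotypeTable(
            sub.individuals + [f"c_{i}" for i in sub.individuals],
            np.concatenate([sub.populations, np.full(len(sub.individuals), "copy")]),
            sub.loci, np.concatenate([sub.alleles, sub.alleles]))
        theta = pairwise_fst(dup)
        assert theta.values[0, 1] <= 0
        assert theta.clipped().values[0, 1] == 0.0

    def test_fixed_differences_all_loci(self):
        gt = make_gt({"P": [[(1, 1), (3, 3)]] * 6, "Q": [[(2, 2), (4, 4)]] * 6},
                     loci=["A", "B"])
        assert pairwise_fst(gt).values[0, 1] == pytest.approx(1.0)

    def test_matches_independent_wc_formula(self, tiny_gt):
        ours = multilocus_theta(tiny_gt)
        pops = {p: tiny_gt.alleles[tiny_gt.populations == p]
                for p in tiny_gt.population_labels}
        oracle = wc_theta_direct(pops)
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_rank_agreement_with_gst(self, island_genotypes):
        """theta and G_ST rank population pairs consistently."""
        from scipy.stats import spearmanr

        gt, _ = island_genotypes
        theta = pairwise_fst(gt)
        pops = gt.population_labels
        import itertools

        g_vals, t_vals = [], []
        for a, b in itertools.combinations(pops, 2):
            sub = gt.subset_populations([a, b])
            g_vals.append(gst(sub).multilocus_gst)
            t_vals.append(theta[a, b])
        rho = spearmanr(g_vals, t_vals).statistic
        assert rho > 0.8


class TestNeiDistance:
    def test_identical_populations_zero(self):
        genos = [(1, 2)] * 4 + [(1, 1)] * 4
        gt = make_gt({"P": genos, "Q": genos})
        assert nei_distance(gt).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_infinite_masked(self):
        gt = make_gt({"P": [(1, 1)] * 4, "Q": [(2, 2)] * 4})
        dm = nei_distance(gt)
        assert dm.mask[0, 1]

    def test_matches_identity_composition(self):
        gt = make_gt({
            "P": [[(1, 1), (1, 2)], [(1, 2), (2, 2)], [(1, 1), (1, 1)]],
            "Q": [[(2, 2), (2, 2)], [(1, 2), (1, 2)], [(1, 2), (2, 2)]],
        }, loci=["A", "B"])
        freqs = {}
        for pop in ("P", "Q"):
            sel = gt.alleles[gt.populations == pop]
            per_locus = []
            for l in range(2):
                vals = sel[:, l, :].ravel()
                per_locus.append(np.array([(vals == a).mean()
                                           for a in sorted(set(vals))]))
            freqs[pop] = per_locus
        expected = nei_identity_distance(freqs["P"], freqs["Q"])
        assert nei_distance(gt).values[0, 1] == pytest.approx(expected, rel=1e-12)
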