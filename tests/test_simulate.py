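import numpy as np
import pandas as pd
import pytest

from meliapop.markers import hwe_tests, multilocus_theta
from meliapop.matrices import mantel
from meliapop.geo import climate_distance_matrices, geographic_distance_matrix
from meliapop.simulate import (GardenSimConfig, MarkerSimConfig,
                               TrueParameters, default_ancestral_freqs,
                               simulate_allele_freqs, simulate_common_garden,
                               simulate_genotypes, simulate_geography_climate,
                               simulate_markers, simulate_survival_trait)


class TestMarkerConfig:
    def test_rejects_bad_fst(self):
        with pytest.raises(ValueError, match="target_fst"):
            MarkerSimConfig(target_fst=1.0)

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError, match="probability"):
            MarkerSimConfig(n_loci=1, ancestral_allele_freqs=[np.array([0.5, 0.6])])

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError, match="counts"):
            MarkerSimConfig(n_pops=0)


class TestAlleleFreqs:
    def test_fst_zero_returns_ancestral(self):
        anc = default_ancestral_freqs(4, seed=1)
        cfg = MarkerSimConfig(n_pops=6, n_loci=4, target_fst=0.0,
                              ancestral_allele_freqs=anc, seed=1)
        freqs = simulate_allele_freqs(cfg)
        for p, f in zip(anc, freqs):
            assert np.allclose(f, np.tile(p, (6, 1)))

    def test_degenerate_simplex_stays_monomorphic(self):
        cfg = MarkerSimConfig(n_pops=5, n_loci=1, target_fst=0.2,
                              ancestral_allele_freqs=[np.array([1.0])], seed=0)
        freqs = simulate_allele_freqs(cfg)
        assert np.allclose(freqs[0], 1.0)

    def test_vectors_sum_to_one(self):
        cfg = MarkerSimConfig(n_pops=10, n_loci=5, target_fst=0.3, seed=2)
        for f in simulate_allele_freqs(cfg):
            assert np.allclose(f.sum(axis=1), 1.0)


class TestGenotypes:
    def test_monomorphic_locus_all_homozygous(self):
        freqs = [np.ones((3, 1))]
        gt = simulate_genotypes(freqs, 10, seed=0)
        assert (gt.alleles[:, 0, 0] == gt.alleles[:, 0, 1]).all()

    def test_heterozygote_fraction_binomial(self):
        n = 4000
        freqs = [np.array([[0.5, 0.5]])]
        gt = simulate_genotypes(freqs, n, seed=1)
        het = (gt.alleles[:, 0, 0] != gt.alleles[:, 0, 1]).mean()
        sd = np.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) < 3 * sd

    def test_same_seed_identical(self):
        cfg = MarkerSimConfig(n_pops=4, n_loci=6, n_per_pop=8, seed=9)
        a, _ = simulate_markers(cfg)
        b, _ = simulate_markers(MarkerSimConfig(n_pops=4, n_loci=6,
                                                n_per_pop=8, seed=9))
        np.testing.assert_array_equal(a.alleles, b.alleles)
        assert a.individuals == b.individuals

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError, match="n_per_pop"):
            simulate_genotypes([np.ones((2, 1))], 0)

    def test_within_population_hwe_calibrated(self):
        """Simulated genotypes are in HWE within populations."""
        cfg = MarkerSimConfig(n_pops=6, n_loci=10, n_per_pop=25,
                              target_fst=0.1, seed=33)
        gt, _ = simulate_markers(cfg)
        df = hwe_tests(gt, method="exact_mc", n_mc=1000, seed=0)
        ok = df[df["applicable"]]
        rate = (ok["p"] < 0.05).mean()
        assert rate <= 0.10  # ~alpha, conservative exact test


class TestFstDial:
    @pytest.mark.parametrize("target", [0.02, 0.2])
    def test_theta_recovers_target(self, target):
        """Mean multilocus theta over replicates lands on the F dial."""
        thetas = []
        for seed in range(25):
            cfg = MarkerSimConfig(n_pops=20, n_loci=15, n_per_pop=15,
                                  target_fst=target, seed=seed)
            gt, _ = simulate_markers(cfg)
            thetas.append(multilocus_theta(gt))
        assert abs(np.mean(thetas) - target) < 0.03


class TestGarden:
    def test_all_zero_variances_constant(self):
        cfg = GardenSimConfig(n_prov=3, families_per_prov=2, n_blocks=2,
                              n_per_family_block=2, var_provenance=0.0,
                              var_family=0.0, var_residual=0.0,
                              grand_mean=7.5, seed=0)
        tt, _ = simulate_common_garden(cfg)
        assert (tt["value"] == 7.5).all()

    def test_true_qst_formula(self):
        cfg = GardenSimConfig(var_provenance=0.5, var_family=0.0625)
        assert cfg.true_qst == pytest.approx(0.5)

    def test_family_vector_length_checked(self):
        with pytest.raises(ValueError, match="families_per_prov"):
            GardenSimConfig(n_prov=3, families_per_prov=[2, 2])

    def test_unbalanced_family_counts_respected(self):
        cfg = GardenSimConfig(n_prov=3, families_per_prov=[1, 4, 2],
                              n_blocks=2, n_per_family_block=2, seed=1)
        tt, _ = simulate_common_garden(cfg)
        fam_counts = (tt.drop_duplicates(["provenance", "family"])
                      .groupby("provenance").size())
        assert sorted(fam_counts) == [1, 2, 4]

    def test_missing_rate_thins(self):
        cfg = GardenSimConfig(n_prov=4, families_per_prov=4, n_blocks=4,
                              n_per_family_block=4, missing_rate=0.3, seed=2)
        tt, _ = simulate_common_garden(cfg)
        full = 4 * 4 * 4 * 4
        assert 0.55 * full < len(tt) < 0.85 * full

    def test_same_seed_identical_table(self):
        cfg = dict(n_prov=4, families_per_prov=3, n_blocks=3,
                   n_per_family_block=2, seed=77)
        a, _ = simulate_common_garden(GardenSimConfig(**cfg))
        b, _ = simulate_common_garden(GardenSimConfig(**cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_survival_trait_binary(self):
        cfg = GardenSimConfig(n_prov=4, families_per_prov=3, n_blocks=3,
                              n_per_family_block=2, grand_mean=0.5, seed=5)
        tt, _ = simulate_survival_trait(cfg)
        assert set(tt["value"]) <= {0.0, 1.0}
        assert tt["trait"].eq("SR").all()

    def test_truth_round_trips_through_yaml(self, tmp_path):
        cfg = GardenSimConfig(n_prov=3, families_per_prov=2, n_blocks=2,
                              n_per_family_block=2, seed=3)
        _, truth = simulate_common_garden(cfg)
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        back = TrueParameters.from_yaml(path)
        assert back.var_provenance == truth.var_provenance
        assert back.provenance_effects == truth.provenance_effects


class TestGeographyClimate:
    def test_noiseless_linear_climate_proportional_to_latitude(self):
        meta, climate = simulate_geography_climate(
            8, seed=4, climate_spec={"v": (2.0, 0.0)})
        lat = np.array([m.latitude for m in meta])
        dm = climate_distance_matrices(climate)["v"]
        dl = np.abs(lat[:, None] - lat[None, :])
        assert np.allclose(dm.values, 2.0 * dl)

    def test_two_identical_coordinates_zero_distance(self):
        meta, _ = simulate_geography_climate(3, seed=0)
        from meliapop.geo import PopulationMeta, chord_distance

        clone = PopulationMeta("x", meta[0].latitude, meta[0].longitude,
                               meta[0].elevation)
        assert chord_distance(meta[0], clone) == 0.0

    def test_zero_slope_mantel_null(self):
        """Slope-0 climate is uncorrelated with geography over replicates."""
        rs = []
        for seed in range(30):
            meta, climate = simulate_geography_climate(
                10, seed=seed, climate_spec={"v": (0.0, 1.0)})
            geo = geographic_distance_matrix(meta)
            cdm = climate_distance_matrices(climate)["v"]
            rs.append(mantel(cdm, geo, n_perm=99, seed=seed).r)
        assert abs(np.mean(rs)) < 0.1

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="climate_spec"):
            simulate_geography_climate(5, climate_spec={})

    def test_needs_two_populations(self):
        with pytest.raises(ValueError, match="n_pops"):
            simulate_geography_climate(1)
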