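import numpy as np
import pandas as pd
import pytest

from oracles import henderson_varcomp

from meliapop.quantgen import (annual_qst_summary, fit_varcomp,
                               pairwise_qst, qst_from_varcomp,
                               validate_trait_table)
from meliapop.simulate import GardenSimConfig, simulate_common_garden


class TestQstFormula:
    @pytest.mark.parametrize("s2p,s2f,expected", [
        (0.0, 0.3, 0.0),
        (0.7, 0.0, 1.0),
        (0.8, 0.1, 0.5),       # s2_P = 8 s2_F
        (0.5, 0.0625, 0.5),
    ])
    def test_values(self, s2p, s2f, expected):
        assert qst_from_varcomp((s2p, s2f)) == pytest.approx(expected)

    def test_undefined_at_zero_denominator(self):
        with pytest.raises(ValueError, match="undefined"):
            qst_from_varcomp((0.0, 0.0))


class TestFitVarcomp:
    def test_matches_henderson_on_balanced_data(self, garden_table):
        """REML equals sequential-SS moment estimates on balanced data."""
        tt, truth, cfg = garden_table
        vc = fit_varcomp(tt, "HEIT", 1)
        s2p, s2f, s2e = henderson_varcomp(tt, "HEIT", 1)
        assert vc.converged
        assert vc.sigma2_P == pytest.approx(s2p, rel=1e-4)
        assert vc.sigma2_F == pytest.approx(s2f, rel=1e-4)
        assert vc.sigma2_E == pytest.approx(s2e, rel=1e-4)

    def test_zero_provenance_variance_hits_boundary(self):
        cfg = GardenSimConfig(n_prov=10, families_per_prov=6, n_blocks=4,
                              n_per_family_block=3, var_provenance=0.0,
                              var_family=0.2, var_residual=1.0, seed=9)
        tt, _ = simulate_common_garden(cfg)
        vc = fit_varcomp(tt, "HEIT", 1)
        assert vc.sigma2_P < 0.01 * vc.sigma2_E

    def test_single_provenance_errors(self, garden_table):
        tt, _, _ = garden_table
        one = tt[tt["provenance"] == "prov01"]
        with pytest.raises(ValueError, match="provenances"):
            fit_varcomp(one, "HEIT", 1)

    def test_block_effect_recovery(self):
        cfg = GardenSimConfig(n_prov=6, families_per_prov=4, n_blocks=4,
                              n_per_family_block=4, var_provenance=0.3,
                              var_family=0.1, var_residual=0.5,
                              block_effects=[0.0, 1.0, 2.0, 3.0], seed=13)
        tt, _ = simulate_common_garden(cfg)
        vc = fit_varcomp(tt, "HEIT", 1)
        # treatment coding: b02..b04 relative to baseline b01
        assert vc.block_effects["b02"] == pytest.approx(1.0, abs=0.3)
        assert vc.block_effects["b04"] == pytest.approx(3.0, abs=0.3)

    def test_qst_affine_invariance(self, garden_table):
        """Q_ST is unchanged by y -> a*y + b."""
        tt, _, _ = garden_table
        q0 = fit_varcomp(tt, "HEIT", 1).qst
        tt2 = tt.copy()
        tt2["value"] = 3.7 * tt2["value"] - 12.0
        q1 = fit_varcomp(tt2, "HEIT", 1).qst
        assert q1 == pytest.approx(q0, rel=1e-5)

    def test_deterministic(self, garden_table):
        tt, _, _ = garden_table
        a = fit_varcomp(tt, "HEIT", 1)
        b = fit_varcomp(tt, "HEIT", 1)
        assert (a.sigma2_P, a.sigma2_F, a.sigma2_E) == \
               (b.sigma2_P, b.sigma2_F, b.sigma2_E)


class TestValidation:
    def test_duplicate_key_rejected(self, garden_table):
        tt, _, _ = garden_table
        bad = pd.concat([tt, tt.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            validate_trait_table(bad)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_trait_table(pd.DataFrame({"value": [1.0]}))


class TestPairwiseQst:
    def test_pair_count(self, garden_table):
        tt, _, cfg = garden_table
        qm = pairwise_qst(tt, "HEIT", 1)
        n = cfg.n_prov
        tri = qm.matrix.triangle()
        assert len(tri) == n * (n - 1) // 2

    def test_identical_provenances_near_zero(self):
        """Two provenances with equal effects: pairwise Q_ST ~ 0."""
        cfg = GardenSimConfig(n_prov=2, families_per_prov=8, n_blocks=5,
                              n_per_family_block=4, var_provenance=0.0,
                              var_family=0.25, var_residual=1.0, seed=17)
        tt, _ = simulate_common_garden(cfg)
        qm = pairwise_qst(tt, "HEIT", 1)
        val = qm.matrix.triangle()
        if np.isfinite(val[0]):
            assert val[0] < 0.25

    def test_single_family_pair_flagged(self):
        cfg = GardenSimConfig(n_prov=3, families_per_prov=[1, 4, 4],
                              n_blocks=4, n_per_family_block=3,
                              var_provenance=0.4, var_family=0.1,
                              var_residual=1.0, seed=3)
        tt, _ = simulate_common_garden(cfg)
        qm = pairwise_qst(tt, "HEIT", 1)
        assert (qm.flags["reason"] == "single_family_member").sum() == 2
        assert qm.matrix.mask[0, 1]

    def test_tracks_true_effect_separation(self):
        """Pairs of far-apart provenance effects get larger Q_ST."""
        cfg = GardenSimConfig(n_prov=6, families_per_prov=6, n_blocks=5,
                              n_per_family_block=4, var_provenance=1.5,
                              var_family=0.1, var_residual=0.8, seed=29)
        tt, truth = simulate_common_garden(cfg)
        qm = pairwise_qst(tt, "HEIT", 1)
        eff = truth.provenance_effects
        import itertools

        seps, qsts = [], []
        for a, b in itertools.combinations(qm.matrix.labels, 2):
            if np.isfinite(qm.matrix[a, b]):
                seps.append(abs(eff[a] - eff[b]))
                qsts.append(qm.matrix[a, b])
        r = np.corrcoef(seps, qsts)[0, 1]
        assert r > 0.3


class TestAnnualSummary:
    def test_single_pair_dataset(self):
        cfg = GardenSimConfig(n_prov=2, families_per_prov=5, n_blocks=4,
                              n_per_family_block=3, var_provenance=0.5,
                              var_family=0.1, var_residual=1.0, seed=31)
        tt, _ = simulate_common_garden(cfg)
        summary = annual_qst_summary(tt)
        qm = pairwise_qst(tt, "HEIT", 1)
        assert summary["mean_pairwise_qst"].iloc[0] == pytest.approx(
            qm.matrix.triangle()[0])

    def test_constant_trait_flagged(self):
        cfg = GardenSimConfig(n_prov=3, families_per_prov=3, n_blocks=2,
                              n_per_family_block=2, var_provenance=0.0,
                              var_family=0.0, var_residual=0.0,
                              grand_mean=5.0, seed=1)
        tt, _ = simulate_common_garden(cfg)
        summary = annual_qst_summary(tt)
        assert summary["trait_mean"].iloc[0] == pytest.approx(5.0)
        assert np.isnan(summary["mean_pairwise_qst"].iloc[0])

    def test_monotone_qst_with_growing_divergence(self):
        """A multi-year panel with rising s2_P shows rising mean Q_ST."""
        frames = []
        for year, s2p in [(1, 0.02), (2, 0.6), (3, 6.0)]:
            cfg = GardenSimConfig(n_prov=6, families_per_prov=5, n_blocks=4,
                                  n_per_family_block=3, var_provenance=s2p,
                                  var_family=0.1, var_residual=1.0,
                                  year=year, seed=100 + year)
            tt, _ = simulate_common_garden(cfg)
            frames.append(tt)
        panel = pd.concat(frames, ignore_index=True)
        panel["individual_id"] = [f"r{k}" for k in range(len(panel))]
        summary = annual_qst_summary(panel).sort_values("year")
        q = summary["mean_pairwise_qst"].to_numpy()
        assert q[0] < q[1] < q[2]
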