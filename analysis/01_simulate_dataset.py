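#!/usr/bin/env python
"""Simulate a study-scale dataset with known ground truth.

Generates the three inputs every later step consumes, at the dimensions of
the real trial: 31 marker populations of 15 diploids at 15 SSR loci with
the island-model drift dial set to 0.086; a common garden of 22
provenances with the trial's unbalanced family counts (1-26 per
provenance, 236 total), 10 blocks, 5 trees per family and block; and
coordinates/climate for the 31 populations.  Everything is written under
results/dataset/ together with a truth sidecar.
"""

from pathlib import Path

import pandas as pd

from meliapop.simulate import (GARDEN_FAMILY_COUNTS, GardenSimConfig,
                               MarkerSimConfig, simulate_common_garden,
                               simulate_geography_climate, simulate_markers)

SEED = 20221022
OUT = Path("results/dataset")


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    mcfg = MarkerSimConfig(n_pops=31, n_loci=15, n_per_pop=15,
                           target_fst=0.086, seed=SEED)
    gt, truth = simulate_markers(mcfg)
    gt.write_genalex(OUT / "genotypes.csv")

    gcfg = GardenSimConfig(n_prov=22, families_per_prov=GARDEN_FAMILY_COUNTS,
                           n_blocks=10, n_per_family_block=5,
                           var_provenance=0.5, var_family=0.0625,
                           var_residual=1.0, grand_mean=10.0, seed=SEED)
    tt, gtruth = simulate_common_garden(gcfg)
    # garden provenances are the first 22 marker populations
    pops = gt.population_labels[:22]
    tt["provenance"] = tt["provenance"].map(
        dict(zip([f"prov{j + 1:02d}" for j in range(22)], pops)))
    tt.to_csv(OUT / "traits.csv", index=False)

    meta, climate = simulate_geography_climate(31, seed=SEED)
    pd.DataFrame([m.__dict__ for m in meta]).to_csv(OUT / "population_meta.csv",
                                                    index=False)
    climate.to_csv(OUT / "climate.csv", index=False)

    truth.var_provenance = gtruth.var_provenance
    truth.var_family = gtruth.var_family
    truth.var_residual = gtruth.var_residual
    truth.true_qst = gtruth.true_qst
    truth.provenance_effects = gtruth.provenance_effects
    truth.to_yaml(OUT / "truth.yaml")

    print(f"wrote {OUT}/: {len(gt.individuals)} genotyped trees across "
          f"{len(gt.population_labels)} populations, "
          f"{len(tt)} garden observations across 22 provenances "
          f"(true Q_ST = {gcfg.true_qst:.3f}, F dial = {mcfg.target_fst})")


if __name__ == "__main__":
    main()
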