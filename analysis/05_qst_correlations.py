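#!/usr/bin/env python
"""Q_ST distance matrices against geography and climate.

Correlates the pairwise Q_ST matrix with the chord-distance matrix and
with each per-variable climate distance matrix (Mantel permutation
p-values, star notation), mirroring the study's trait x predictor grids.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from meliapop.distmat import DistanceMatrix
from meliapop.geo import (climate_distance_matrices,
                          geographic_distance_matrix, read_population_meta)
from meliapop.matrices import qst_correlation_table

OUT = Path("results")
SEED = 20221022


def main():
    qst = DistanceMatrix.read_csv(OUT / "qst_pairwise_HEIT1.csv")
    meta = read_population_meta(OUT / "dataset/population_meta.csv")
    geo = geographic_distance_matrix(meta)
    climate = pd.read_csv(OUT / "dataset/climate.csv",
                          dtype={"population": str})
    preds = {"geography": geo}
    preds.update(climate_distance_matrices(climate))

    # restrict predictors to the 22 garden provenances
    sub = {}
    for name, dm in preds.items():
        idx = [dm.labels.index(l) for l in qst.labels]
        sub[name] = DistanceMatrix(qst.labels, dm.values[np.ix_(idx, idx)],
                                   dm.mask[np.ix_(idx, idx)])
    tab = qst_correlation_table({("HEIT", 1): qst}, sub, n_perm=9999,
                                seed=SEED)
    tab.to_csv(OUT / "qst_correlations.csv", index=False)
    print(tab.to_string(index=False))
    print("(provenance effects were drawn independently of geography, so "
          "near-zero r with 'ns' stars is the expected truth here)")


if __name__ == "__main__":
    main()
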