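#!/usr/bin/env python
"""Q_ST - F_ST neutrality test for the garden trait.

Builds the neutral null (locus-bootstrap F_ST*, chi-square mean-square
resampling of the variance components conditioned on E[Q_ST] = F_ST*),
locates the observed difference, and prints the report row next to the
published table's format.  The simulated trait has true Q_ST = 0.5
against F_ST ~ 0.086, so a divergent-selection call is the correct
outcome.
"""

from pathlib import Path

import pandas as pd

from meliapop.markers import read_genotypes
from meliapop.qstfst import qst_fst_test, qstfst_table
from meliapop.reference import qstfst_observed_table

OUT = Path("results")
SEED = 20221022


def main():
    gt = read_genotypes(OUT / "dataset/genotypes.csv", dialect="genalex")
    tt = pd.read_csv(OUT / "dataset/traits.csv",
                     dtype={"provenance": str, "family": str, "block": str})
    gsub = gt.subset_populations(sorted(tt["provenance"].unique()))
    res = qst_fst_test(tt, gsub, "HEIT", 1, n_resamples=10_000, seed=SEED)
    tab = qstfst_table([res])
    tab.to_csv(OUT / "qstfst_table.csv", index=False)
    print(tab.to_string(index=False))
    print(f"observed Q_ST = {res.observed_qst:.4f}, "
          f"F_ST = {res.observed_fst:.4f}, null mean = {res.null_mean:.2e}")
    pub = qstfst_observed_table()
    print(f"(published table spans {len(pub)} trait-years with critical "
          f"bounds around [-0.06, 0.09]; the simulated trait is built far "
          f"from neutrality, hence the divergent call)")


if __name__ == "__main__":
    main()
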