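"""Published summary tables from the chinaberry range-wide study.

The study deposited no raw genotypes or trial measurements, but its
printed per-population and per-locus summaries are usable as inputs:
the diversity table drives the worked aggregation example, the sampling
sites drive the geographic distance matrix, and the per-locus
differentiation table anchors the isolation-by-distance regression.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .geo import PopulationMeta, _coord

__all__ = [
    "diversity_table",
    "locus_differentiation_table",
    "population_sites",
    "ssr_population_meta",
    "qstfst_observed_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("meliapop.data").joinpath(name).open("r",
                                                              encoding="utf-8") as fh:
        return pd.read_csv(fh)


def diversity_table() -> pd.DataFrame:
    """Per-population SSR diversity summaries (31 populations, 15 loci).

    Columns: na/ne (observed and effective alleles), he (unbiased expected
    heterozygosity), h (gene diversity), i (Shannon), pic, with SDs over
    loci where published.
    """
    df = _read("diversity_by_population.csv")
    df["population"] = df["population"].astype(str)
    return df


def locus_differentiation_table() -> pd.DataFrame:
    """Per-locus G_ST and IBD regression coefficients, plus a multilocus row.

    ``a`` and ``b`` are intercept and slope of G_ST/(1-G_ST) on
    ln(geographic distance), ``r`` the matrix correlation, ``p`` its
    permutation p-value.
    """
    return _read("locus_differentiation.csv")


def population_sites() -> pd.DataFrame:
    """All sampled sites with degree-minute coordinates and elevation (m)."""
    df = _read("population_sites.csv")
    df["population"] = df["population"].astype(str)
    return df


def ssr_population_meta() -> list[PopulationMeta]:
    """Metadata for the 31 populations genotyped at the SSR loci."""
    df = population_sites()
    df = df[df["experiments"].apply(lambda s: "I" in str(s).split())]
    return [
        PopulationMeta(row["population"], _coord(row["latitude"]),
                       _coord(row["longitude"]), float(row["elevation"]))
        for _, row in df.iterrows()
    ]


def qstfst_observed_table() -> pd.DataFrame:
    """Published Q_ST - F_ST comparison per trait-year (30 trait codes)."""
    return _read("qstfst_observed.csv")
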