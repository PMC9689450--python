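"""Synthetic datasets with known ground truth.

The study's raw genotypes and trial measurements are not deposited, so every
downstream stage is exercised on simulated data whose generating parameters
are recorded alongside the output.

Markers follow a Balding-Nichols island model: population allele-frequency
vectors are Dirichlet draws around a shared ancestral vector with
concentration p_a (1-F)/F, which makes the drift parameter F a direct dial
for the expected multilocus F_ST.  Genotypes are two independent allele
draws per diploid (Hardy-Weinberg within populations).

Phenotypes follow the provenance-trial observation model

    Y_ijkl = mu + B_i + P_j + F_k(j) + E_ijkl

with fixed block offsets B_i, provenance effects P_j ~ N(0, s2_P), family
within provenance F_k(j) ~ N(0, s2_F) and residual E ~ N(0, s2_E).  Under a
half-sib (open-pollinated dam) design the additive variance is ~4 s2_F,
hence the trait differentiation index Q_ST = s2_P / (s2_P + 8 s2_F).

Default configurations match the study conditions: 31 marker populations of
15 diploids at 15 highly polymorphic SSR loci with multilocus
differentiation near 0.086, and a garden of 22 provenances, an unbalanced
1-26 families per provenance (236 total), 10 blocks, 5 trees per family and
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geo import PopulationMeta
from .markers import GenotypeTable

__all__ = [
    "MarkerSimConfig",
    "GardenSimConfig",
    "TrueParameters",
    "default_ancestral_freqs",
    "simulate_allele_freqs",
    "simulate_genotypes",
    "simulate_markers",
    "simulate_common_garden",
    "simulate_geography_climate",
    "GARDEN_FAMILY_COUNTS",
]

# families per provenance in the trial design (unbalanced, 236 in total)
GARDEN_FAMILY_COUNTS = [16, 20, 22, 16, 10, 7, 11, 9, 26, 4,
                        1, 9, 7, 4, 3, 8, 9, 18, 19, 10, 3, 4]

_SIMPLEX_TOL = 1e-12


def _spawn(seed: int, *path: int) -> np.random.Generator:
    """Deterministic child stream: one global seed, keyed sub-streams."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=path))


@dataclass
class MarkerSimConfig:
    """Island-model marker simulation settings.

    ``ancestral_allele_freqs`` is one probability vector per locus; use
    :func:`default_ancestral_freqs` for highly polymorphic SSR-like loci
    (8 alleles, expected heterozygosity ~ 0.84).
    """

    n_pops: int = 31
    n_loci: int = 15
    n_per_pop: int = 15
    target_fst: float = 0.086
    ancestral_allele_freqs: list[np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pops, self.n_loci, self.n_per_pop) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        if self.ancestral_allele_freqs is None:
            self.ancestral_allele_freqs = default_ancestral_freqs(
                self.n_loci, seed=self.seed)
        if len(self.ancestral_allele_freqs) != self.n_loci:
            raise ValueError("need one ancestral frequency vector per locus")
        self.ancestral_allele_freqs = [
            np.asarray(p, dtype=float) for p in self.ancestral_allele_freqs
        ]
        for l, p in enumerate(self.ancestral_allele_freqs):
            if (p < 0).any() or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"locus {l}: ancestral frequencies are not a "
                                 "probability vector")


def default_ancestral_freqs(n_loci: int, n_alleles: int = 8,
                            concentration: float = 3.0, seed: int = 0
                            ) -> list[np.ndarray]:
    """Dirichlet ancestral vectors for SSR-like multiallelic loci.

    With 8 alleles and concentration 3 the expected gene diversity is
    1 - (c+1)/(k c+1) = 0.84, matching highly polymorphic microsatellites.
    """
    rng = _spawn(seed, 0)
    out = []
    for _ in range(n_loci):
        p = rng.dirichlet(np.full(n_alleles, concentration))
        out.append(p / p.sum())
    return out


def simulate_allele_freqs(cfg: MarkerSimConfig) -> list[np.ndarray]:
    """Per-population allele frequencies, one (n_pops, k_l) array per locus.

    Balding-Nichols: population vectors ~ Dirichlet(p_a (1-F)/F).  F = 0
    returns the ancestral vectors unchanged (no drift).
    """
    rng = _spawn(cfg.seed, 1)
    F = cfg.target_fst
    out = []
    for p in cfg.ancestral_allele_freqs:
        if F == 0:
            out.append(np.tile(p, (cfg.n_pops, 1)))
            continue
        support = p > 0
        freqs = np.zeros((cfg.n_pops, len(p)))
        if support.sum() == 1:
            freqs[:, support] = 1.0  # degenerate simplex: stays monomorphic
        else:
            alpha = p[support] * (1 - F) / F
            freqs[:, support] = rng.dirichlet(alpha, size=cfg.n_pops)
        out.append(freqs)
    return out


def simulate_genotypes(freqs: list[np.ndarray], n_per_pop: int, seed: int = 0,
                       pop_labels=None, loci=None) -> GenotypeTable:
    """Draw diploid genotypes from per-population frequencies (HWE within pop).

    Allele codes are 1-based column indices of the frequency vectors.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    n_pops = freqs[0].shape[0]
    rng = _spawn(seed, 2)
    if pop_labels is None:
        pop_labels = [f"pop{j + 1:02d}" for j in range(n_pops)]
    if loci is None:
        loci = [f"SSR{l + 1:02d}" for l in range(len(freqs))]
    n = n_pops * n_per_pop
    alleles = np.zeros((n, len(freqs), 2), dtype=int)
    individuals, populations = [], []
    for j in range(n_pops):
        for i in range(n_per_pop):
            individuals.append(f"{pop_labels[j]}_{i + 1:03d}")
            populations.append(pop_labels[j])
    for l, p in enumerate(freqs):
        for j in range(n_pops):
            rows = slice(j * n_per_pop, (j + 1) * n_per_pop)
            draws = rng.choice(len(p[j]), size=(n_per_pop, 2), p=p[j]) + 1
            alleles[rows, l, :] = draws
    return GenotypeTable(individuals, np.array(populations), list(loci), alleles)


def simulate_markers(cfg: MarkerSimConfig):
    """Convenience: frequencies + genotypes + truth record in one call."""
    freqs = simulate_allele_freqs(cfg)
    gt = simulate_genotypes(freqs, cfg.n_per_pop, seed=cfg.seed)
    truth = TrueParameters(target_fst=cfg.target_fst,
                           allele_freqs={f"SSR{l + 1:02d}": f.tolist()
                                         for l, f in enumerate(freqs)})
    return gt, truth


# ---------------------------------------------------------------------------
# common garden
# ---------------------------------------------------------------------------

@dataclass
class GardenSimConfig:
    """Provenance-trial simulation settings.

    ``families_per_prov`` may be a single count or a per-provenance vector
    (the trial itself had 1-26 families per provenance).
    """

    n_prov: int = 22
    families_per_prov: int | list[int] = field(
        default_factory=lambda: list(GARDEN_FAMILY_COUNTS))
    n_blocks: int = 10
    n_per_family_block: int = 5
    grand_mean: float = 10.0
    block_effects: list[float] | None = None
    var_provenance: float = 0.5
    var_family: float = 0.0625
    var_residual: float = 1.0
    trait: str = "HEIT"
    year: int = 1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.families_per_prov, int):
            self.families_per_prov = [self.families_per_prov] * self.n_prov
        if len(self.families_per_prov) != self.n_prov:
            raise ValueError("families_per_prov length must equal n_prov")
        if min(self.families_per_prov) < 1:
            raise ValueError("each provenance needs >= 1 family")
        for v in (self.var_provenance, self.var_family, self.var_residual):
            if v < 0:
                raise ValueError("variances must be >= 0")
        if self.block_effects is None:
            self.block_effects = [0.0] * self.n_blocks
        if len(self.block_effects) != self.n_blocks:
            raise ValueError("block_effects length must equal n_blocks")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def true_qst(self) -> float:
        denom = self.var_provenance + 8 * self.var_family
        if denom == 0:
            return np.nan
        return self.var_provenance / denom


@dataclass
class TrueParameters:
    """Ground truth stored beside every simulated dataset."""

    target_fst: float | None = None
    allele_freqs: dict | None = None
    var_provenance: float | None = None
    var_family: float | None = None
    var_residual: float | None = None
    true_qst: float | None = None
    provenance_effects: dict | None = None
    block_effects: list | None = None

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if v is not None}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrueParameters":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def simulate_common_garden(cfg: GardenSimConfig):
    """Simulate one trait-year of a randomized-block provenance trial.

    Returns ``(trait_table, truth)``: a long-format DataFrame with columns
    individual_id, provenance, family, block, year, trait, value, and the
    generating parameters.  ``missing_rate`` thins observations at random
    to emulate mortality.
    """
    rng = _spawn(cfg.seed, 3)
    provs = [f"prov{j + 1:02d}" for j in range(cfg.n_prov)]
    P = rng.normal(0.0, np.sqrt(cfg.var_provenance), size=cfg.n_prov)
    fam_effects = {}
    for j, nf in enumerate(cfg.families_per_prov):
        fam_effects[provs[j]] = rng.normal(0.0, np.sqrt(cfg.var_family), size=nf)
    rows = []
    serial = 0
    for j, prov in enumerate(provs):
        for k in range(cfg.families_per_prov[j]):
            fam = f"{prov}_f{k + 1:02d}"
            for b in range(cfg.n_blocks):
                eps = rng.normal(0.0, np.sqrt(cfg.var_residual),
                                 size=cfg.n_per_family_block)
                for e in eps:
                    serial += 1
                    y = (cfg.grand_mean + cfg.block_effects[b] + P[j]
                         + fam_effects[prov][k] + e)
                    rows.append((f"t{serial:06d}", prov, fam, f"b{b + 1:02d}",
                                 cfg.year, cfg.trait, y))
    tt = pd.DataFrame(rows, columns=["individual_id", "provenance", "family",
                                     "block", "year", "trait", "value"])
    if cfg.missing_rate > 0:
        keep = rng.random(len(tt)) >= cfg.missing_rate
        tt = tt[keep].reset_index(drop=True)
    truth = TrueParameters(
        var_provenance=cfg.var_provenance,
        var_family=cfg.var_family,
        var_residual=cfg.var_residual,
        true_qst=float(cfg.true_qst) if np.isfinite(cfg.true_qst) else None,
        provenance_effects={p: float(v) for p, v in zip(provs, P)},
        block_effects=list(map(float, cfg.block_effects)),
    )
    return tt, truth


def simulate_survival_trait(cfg: GardenSimConfig, threshold: float = 0.0):
    """Threshold-liability binary survival: alive iff latent trait > threshold.

    The latent scale is the same observation model as
    :func:`simulate_common_garden` with ``grand_mean`` interpreted as the
    latent mean; observed values are 0/1.
    """
    tt, truth = simulate_common_garden(cfg)
    tt = tt.copy()
    tt["value"] = (tt["value"] > threshold).astype(float)
    tt["trait"] = "SR"
    return tt, truth


# ---------------------------------------------------------------------------
# geography and climate
# ---------------------------------------------------------------------------

def simulate_geography_climate(n_pops: int, seed: int = 0,
                               climate_spec: dict | None = None,
                               lat_range=(18.0, 39.0), lon_range=(101.0, 120.0),
                               elev_range=(0.0, 2200.0)):
    """Random sites in a lat/lon box plus climate variables tied to latitude.

    ``climate_spec`` maps variable name -> (slope per degree latitude,
    noise SD); variables are ``intercept + slope * lat + N(0, sd)`` so that
    climate distance correlates with geographic distance by construction
    (noise SD 0 with nonzero slope gives an exact linear tie, slope 0 gives
    independence).  Returns (list[PopulationMeta], climate DataFrame).
    """
    if n_pops < 2:
        raise ValueError("need n_pops >= 2")
    if climate_spec is not None and len(climate_spec) == 0:
        raise ValueError("climate_spec must not be empty")
    if climate_spec is None:
        climate_spec = {"mean_temp_c": (-0.7, 0.5), "min_rel_humidity": (0.4, 2.0)}
    rng = _spawn(seed, 4)
    lat = rng.uniform(*lat_range, size=n_pops)
    lon = rng.uniform(*lon_range, size=n_pops)
    elev = rng.uniform(*elev_range, size=n_pops)
    meta = [PopulationMeta(f"pop{j + 1:02d}", float(lat[j]), float(lon[j]),
                           float(elev[j])) for j in range(n_pops)]
    data = {"population": [m.population for m in meta]}
    for var, (slope, sd) in climate_spec.items():
        data[var] = slope * lat + rng.normal(0.0, sd, size=n_pops)
    return meta, pd.DataFrame(data)
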