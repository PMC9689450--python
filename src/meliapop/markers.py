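"""Codominant SSR genotype tables and marker statistics.

Covers the full microsatellite side of the analysis: parsing GenAlEx-style
and long-format genotype files, per-population diversity summaries
(Na, Ne, Ho, He, h, Shannon I, PIC, F_IS), Monte-Carlo exact tests of
Hardy-Weinberg equilibrium with Bonferroni control, Nei-Chesser G_ST,
pairwise Weir-Cockerham theta, and Nei (1972) standard genetic distance.

Formulae per population x locus (allele frequencies p, n diploids typed):

    Na  = number of observed alleles
    Ne  = 1 / sum p^2
    h   = 1 - sum p^2                      (Nei gene diversity)
    He  = 2n/(2n-1) * h                    (unbiased expected heterozygosity)
    Ho  = observed heterozygote fraction
    I   = -sum p ln p                      (Shannon information)
    PIC = 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2
    F_IS = 1 - Ho / h
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix

__all__ = [
    "GenotypeTable",
    "read_genotypes",
    "allele_frequencies",
    "diversity_stats",
    "aggregate_diversity",
    "hwe_tests",
    "gst",
    "pairwise_fst",
    "nei_distance",
    "DiversitySummary",
    "LocusDifferentiation",
]

MISSING = 0  # allele code for a missing call; a genotype is missing iff both are 0


@dataclass
class GenotypeTable:
    """Diploid codominant calls: individuals x loci x 2 allele codes.

    Allele codes are positive integers (allele sizes or arbitrary labels);
    ``(0, 0)`` marks a missing genotype.  Every individual carries the same
    locus set.
    """

    individuals: list[str]
    populations: np.ndarray  # shape (n,), dtype str
    loci: list[str]
    alleles: np.ndarray  # shape (n, n_loci, 2), int

    def __post_init__(self):
        n = len(self.individuals)
        if len(set(self.individuals)) != n:
            dup = pd.Series(self.individuals).value_counts().idxmax()
            raise ValueError(f"duplicate individual id: {dup}")
        self.populations = np.asarray(self.populations, dtype=str)
        self.alleles = np.asarray(self.alleles, dtype=int)
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValueError("alleles array shape mismatch")
        if (self.alleles < 0).any():
            raise ValueError("allele codes must be >= 0")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for {self.individuals[i]} at {self.loci[l]}"
            )

    # -- views -------------------------------------------------------------
    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(str(p), None)
        return list(seen)

    def subset_loci(self, idx) -> "GenotypeTable":
        idx = list(idx)
        return GenotypeTable(
            individuals=[f"{ind}" for ind in self.individuals],
            populations=self.populations.copy(),
            loci=[self.loci[i] for i in idx],
            alleles=self.alleles[:, idx, :].copy(),
        )

    def subset_populations(self, pops) -> "GenotypeTable":
        pops = {str(p) for p in pops}
        keep = np.array([p in pops for p in self.populations])
        return GenotypeTable(
            individuals=[ind for ind, k in zip(self.individuals, keep) if k],
            populations=self.populations[keep],
            loci=list(self.loci),
            alleles=self.alleles[keep],
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.individuals):
            for l, locus in enumerate(self.loci):
                a, b = self.alleles[i, l]
                rows.append((ind, self.populations[i], locus, a, b))
        return pd.DataFrame(
            rows, columns=["individual_id", "population", "locus", "allele1", "allele2"]
        )

    # -- I/O ---------------------------------------------------------------
    def write_genalex(self, path) -> None:
        pops = self.population_labels
        sizes = [int((self.populations == p).sum()) for p in pops]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(",".join(map(str, [len(self.loci), len(self.individuals), len(pops)]
                                  )) + "\n")
            fh.write(",".join(map(str, sizes)) + "\n")
            header = ["individual_id", "population"]
            for locus in self.loci:
                header += [locus, ""]
            fh.write(",".join(header) + "\n")
            for i, ind in enumerate(self.individuals):
                row = [ind, str(self.populations[i])]
                row += [str(a) for a in self.alleles[i].ravel()]
                fh.write(",".join(row) + "\n")

    def write_long(self, path) -> None:
        self.to_long().to_csv(path, index=False)


def read_genotypes(path, dialect: str = "genalex") -> GenotypeTable:
    """Read a genotype CSV.

    ``genalex``: two count header lines (n_loci, n_samples, n_pops / block
    sizes), then a column-header row, then one row per individual with two
    allele columns per locus; missing allele coded 0.
    ``long``: columns individual_id, population, locus, allele1, allele2.
    """
    if dialect == "long":
        df = pd.read_csv(path, dtype={"individual_id": str, "population": str,
                                      "locus": str})
        loci = list(dict.fromkeys(df["locus"]))
        piv = df.set_index(["individual_id", "locus"])
        inds = list(dict.fromkeys(df["individual_id"]))
        pops = df.drop_duplicates("individual_id").set_index("individual_id")[
            "population"]
        alleles = np.zeros((len(inds), len(loci), 2), dtype=int)
        for i, ind in enumerate(inds):
            for l, locus in enumerate(loci):
                try:
                    row = piv.loc[(ind, locus)]
                except KeyError:
                    raise ValueError(f"individual {ind} has no row for locus {locus}")
                alleles[i, l] = (int(row["allele1"]), int(row["allele2"]))
        return GenotypeTable(inds, pops.loc[inds].to_numpy(), loci, alleles)
    if dialect != "genalex":
        raise ValueError(f"unknown dialect: {dialect!r}")

    with open(path, encoding="utf-8") as fh:
        counts = fh.readline().strip().split(",")
        fh.readline()  # per-population sizes; population column is authoritative
        header = fh.readline().rstrip("\n").split(",")
        body = [ln.rstrip("\n").split(",") for ln in fh if ln.strip()]
    n_loci = int(counts[0])
    allele_cols = len(header) - 2
    if allele_cols != 2 * n_loci:
        raise ValueError(
            f"header declares {n_loci} loci but there are {allele_cols} allele columns"
        )
    loci = [header[2 + 2 * l] for l in range(n_loci)]
    inds, pops, allele_rows = [], [], []
    for k, row in enumerate(body):
        if len(row) != 2 + allele_cols:
            raise ValueError(f"row {k + 1} ({row[0]!r}) has {len(row)} fields, "
                             f"expected {2 + allele_cols}")
        inds.append(row[0])
        pops.append(row[1])
        allele_rows.append([int(x) for x in row[2:]])
    alleles = np.array(allele_rows, dtype=int).reshape(len(inds), n_loci, 2)
    return GenotypeTable(inds, np.array(pops), loci, alleles)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _locus_counts(gt: GenotypeTable):
    """Per locus: (pops, allele codes, count matrix, n diploids, het counts).

    Count matrix is populations x alleles (allele copies); individuals with
    a missing genotype at the locus contribute nothing there.
    """
    pops = gt.population_labels
    pop_idx = {p: i for i, p in enumerate(pops)}
    out = []
    for l, locus in enumerate(gt.loci):
        calls = gt.alleles[:, l, :]
        observed = calls[:, 0] != MISSING
        codes = np.unique(calls[observed])
        code_idx = {c: i for i, c in enumerate(codes)}
        counts = np.zeros((len(pops), max(len(codes), 1)), dtype=float)
        n = np.zeros(len(pops), dtype=float)
        het = np.zeros(len(pops), dtype=float)
        for i in np.flatnonzero(observed):
            pi = pop_idx[str(gt.populations[i])]
            a, b = calls[i]
            counts[pi, code_idx[a]] += 1
            counts[pi, code_idx[b]] += 1
            n[pi] += 1
            het[pi] += a != b
        out.append((locus, pops, codes, counts, n, het))
    return out


def allele_frequencies(gt: GenotypeTable) -> pd.DataFrame:
    """Long table: locus, population, allele, count, frequency, n (diploids).

    Population x locus cells with no data are flagged with a single row
    carrying ``n = 0`` and NaN frequency rather than silently dropped.
    """
    rows = []
    for locus, pops, codes, counts, n, _ in _locus_counts(gt):
        for pi, pop in enumerate(pops):
            if n[pi] == 0:
                rows.append((locus, pop, np.nan, 0, np.nan, 0))
                continue
            tot = counts[pi].sum()
            for ci, code in enumerate(codes):
                if counts[pi, ci] > 0:
                    rows.append((locus, pop, code, int(counts[pi, ci]),
                                 counts[pi, ci] / tot, int(n[pi])))
    return pd.DataFrame(
        rows, columns=["locus", "population", "allele", "count", "frequency", "n"]
    )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Per-locus breakdown plus per-population means +/- SD over loci."""

    per_locus: pd.DataFrame
    per_population: pd.DataFrame


_DIV_STATS = ["na", "ne", "ho", "he", "h", "i", "pic", "fis"]


def diversity_stats(gt: GenotypeTable) -> DiversitySummary:
    rows = []
    for locus, pops, codes, counts, n, het in _locus_counts(gt):
        for pi, pop in enumerate(pops):
            if n[pi] == 0:
                continue
            p = counts[pi] / counts[pi].sum()
            p = p[p > 0]
            sump2 = float((p ** 2).sum())
            h = 1.0 - sump2
            he = 2 * n[pi] / (2 * n[pi] - 1) * h if n[pi] > 0.5 else np.nan
            ho = het[pi] / n[pi]
            shannon = float(-(p * np.log(p)).sum())
            pic = h - float(sum(2 * a * a * b * b
                                for a, b in itertools.combinations(p, 2)))
            fis = 1.0 - ho / h if h > 0 else np.nan
            rows.append((pop, locus, len(p), 1.0 / sump2, ho, he, h, shannon,
                         pic, fis, int(n[pi])))
    per_locus = pd.DataFrame(
        rows, columns=["population", "locus"] + _DIV_STATS + ["n"]
    )
    agg = per_locus.groupby("population", sort=False)[_DIV_STATS].agg(["mean", "std"])
    agg.columns = [f"{s}_{m}" for s, m in agg.columns]
    per_population = agg.reset_index()
    return DiversitySummary(per_locus=per_locus, per_population=per_population)


def aggregate_diversity(per_population: pd.DataFrame) -> pd.DataFrame:
    """Across-population unweighted mean and SD of each diversity statistic.

    Accepts either the ``per_population`` frame from :func:`diversity_stats`
    (``*_mean`` columns) or any frame of one row per population with numeric
    statistic columns, as when aggregating a published summary table.
    """
    df = per_population.copy()
    if df.empty:
        raise ValueError("empty diversity table")
    if "population" in df.columns:
        df = df.drop(columns=["population"])
    num = df.select_dtypes("number")
    out = pd.DataFrame({"mean": num.mean(axis=0), "sd": num.std(axis=0, ddof=1)})
    if len(num) == 1:
        out["sd"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def _pair_log_weight(lo: np.ndarray, hi: np.ndarray, k: int,
                     lgamma_table: np.ndarray) -> float:
    """Log multiplicity weight of a genotype table given its allele counts.

    For fixed allele counts the conditional HWE probability of a genotype
    table is proportional to 2^het / prod(genotype count factorials); only
    this relative weight is needed to rank tables.  Genotypes arrive as
    (min, max) integer codes in [0, k).
    """
    cnt = np.bincount(lo * k + hi, minlength=k * k)
    het = int((lo != hi).sum())
    return het * np.log(2.0) - float(lgamma_table[cnt].sum())


def hwe_exact_mc(pairs: np.ndarray, n_mc: int, rng: np.random.Generator) -> float:
    """Monte-Carlo exact HWE test for one population x locus cell.

    ``pairs`` is (n, 2) observed diploid genotypes.  Alleles are pooled and
    randomly re-paired; each random perfect matching of the allele multiset
    is a draw from the conditional-on-allele-counts HWE distribution.  The
    p-value is the (add-one corrected) fraction of draws whose conditional
    probability is <= the observed one.
    """
    from scipy.special import gammaln

    codes, inv = np.unique(pairs, return_inverse=True)
    k = len(codes)
    inv = inv.reshape(-1, 2)
    lgamma_table = gammaln(np.arange(len(pairs) + 2) + 1.0)
    obs = _pair_log_weight(inv.min(axis=1), inv.max(axis=1), k, lgamma_table)
    alleles = inv.ravel().copy()
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(alleles)
        sim = alleles.reshape(-1, 2)
        lo, hi = sim.min(axis=1), sim.max(axis=1)
        if _pair_log_weight(lo, hi, k, lgamma_table) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def hwe_chi2(pairs: np.ndarray) -> float:
    """Chi-square goodness-of-fit HWE test (fast, asymptotic)."""
    from scipy.stats import chi2 as chi2_dist

    codes, inv = np.unique(pairs, return_inverse=True)
    k = len(codes)
    if k < 2:
        return np.nan
    inv = inv.reshape(pairs.shape)
    n = len(pairs)
    p = np.bincount(inv.ravel(), minlength=k) / (2 * n)
    obs = np.zeros((k, k))
    for a, b in np.sort(inv, axis=1):
        obs[a, b] += 1
    stat = 0.0
    for a in range(k):
        for b in range(a, k):
            exp = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            if exp > 0:
                stat += (obs[a, b] - exp) ** 2 / exp
    df = k * (k - 1) / 2
    return float(chi2_dist.sf(stat, df))


def hwe_tests(gt: GenotypeTable, method: str = "exact_mc", n_mc: int = 100_000,
              seed: int | None = 0, alpha: float = 0.05) -> pd.DataFrame:
    """One HWE test per population x locus cell with a Bonferroni verdict.

    The Bonferroni threshold is ``alpha / (n_pops * n_loci)`` counting every
    cell, including monomorphic ones (which are reported non-applicable).
    Returns a frame with columns population, locus, p, applicable, reject;
    the threshold is attached as ``df.attrs['bonferroni_threshold']``.
    """
    if method not in ("exact_mc", "chi2"):
        raise ValueError(f"unknown method: {method!r}")
    if method == "exact_mc" and n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for exact_mc")
    rng = np.random.default_rng(seed)
    pops = gt.population_labels
    n_tests = len(pops) * len(gt.loci)
    thresh = alpha / n_tests
    rows = []
    for l, locus in enumerate(gt.loci):
        calls = gt.alleles[:, l, :]
        for pop in pops:
            sel = (gt.populations == pop) & (calls[:, 0] != MISSING)
            pairs = calls[sel]
            if len(pairs) == 0 or len(np.unique(pairs)) < 2:
                rows.append((pop, locus, np.nan, False, False))
                continue
            if method == "chi2":
                p = hwe_chi2(pairs)
            else:
                p = hwe_exact_mc(pairs, n_mc, rng)
            rows.append((pop, locus, p, True, bool(p < thresh)))
    df = pd.DataFrame(rows, columns=["population", "locus", "p", "applicable",
                                     "reject"])
    df.attrs["bonferroni_threshold"] = thresh
    df.attrs["n_tests"] = n_tests
    return df


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

@dataclass
class LocusDifferentiation:
    """Per-locus G_ST with the multilocus value from averaged H_S / H_T."""

    per_locus: pd.DataFrame  # locus, hs, ht, gst, n_pops
    multilocus_gst: float
    excluded_loci: list[str] = field(default_factory=list)


def gst(gt: GenotypeTable) -> LocusDifferentiation:
    """Nei-Chesser sample-size-corrected G_ST.

    Per locus with s populations, harmonic-mean sample size n~ and mean
    observed heterozygosity Ho:

        Hs = n~/(n~-1) * (1 - mean_i sum_a p_ia^2 - Ho/(2 n~))
        Ht = 1 - sum_a pbar_a^2 + Hs/(n~ s) - Ho/(2 n~ s)

    The multilocus value is (mean Ht - mean Hs)/mean Ht over loci; globally
    monomorphic loci (Ht = 0) are excluded from the average with a record.
    Negative per-locus estimates are reported as computed.
    """
    rows, excluded = [], []
    for locus, pops, codes, counts, n, het in _locus_counts(gt):
        use = n > 0
        if use.sum() < 2:
            excluded.append(locus)
            rows.append((locus, np.nan, np.nan, np.nan, int(use.sum())))
            continue
        cn, cc, ch = n[use], counts[use], het[use]
        s = len(cn)
        n_h = s / (1.0 / cn).sum()
        p = cc / cc.sum(axis=1, keepdims=True)
        ho = (ch / cn).mean()
        hs = n_h / (n_h - 1) * (1 - (p ** 2).sum(axis=1).mean() - ho / (2 * n_h))
        pbar = p.mean(axis=0)
        ht = 1 - (pbar ** 2).sum() + hs / (n_h * s) - ho / (2 * n_h * s)
        if ht <= 0:
            excluded.append(locus)
            rows.append((locus, hs, ht, np.nan, s))
            continue
        rows.append((locus, hs, ht, (ht - hs) / ht, s))
    per_locus = pd.DataFrame(rows, columns=["locus", "hs", "ht", "gst", "n_pops"])
    ok = per_locus.dropna(subset=["gst"])
    if ok.empty:
        raise ValueError("no polymorphic locus with >= 2 typed populations")
    multi = float((ok["ht"].mean() - ok["hs"].mean()) / ok["ht"].mean())
    return LocusDifferentiation(per_locus=per_locus, multilocus_gst=multi,
                                excluded_loci=excluded)


def wc_locus_components(gt: GenotypeTable) -> pd.DataFrame:
    """Per-locus WC84 variance components (a, b, c) across all populations.

    These are the resampling units for multilocus theta bootstraps: the
    multilocus estimate is sum(a)/sum(a+b+c) over any locus subset.
    """
    rows = []
    for locus, pops, codes, counts, n, hetc in _locus_counts(gt):
        # per-allele heterozygote involvement counts
        het_by_allele = np.zeros_like(counts)
        pop_idx = {p: i for i, p in enumerate(pops)}
        code_idx = {c: i for i, c in enumerate(codes)}
        li = gt.loci.index(locus)
        calls = gt.alleles[:, li, :]
        for i in np.flatnonzero(calls[:, 0] != MISSING):
            aa, bb = calls[i]
            if aa != bb:
                pi = pop_idx[str(gt.populations[i])]
                het_by_allele[pi, code_idx[aa]] += 1
                het_by_allele[pi, code_idx[bb]] += 1
        comp = _wc_allele_components(counts, n, het_by_allele)
        if comp is not None:
            rows.append((locus, *comp))
    if not rows:
        raise ValueError("no locus with >= 2 typed populations")
    return pd.DataFrame(rows, columns=["locus", "a", "b", "c"])


def _wc_allele_components(counts: np.ndarray, n: np.ndarray,
                          het_by_allele: np.ndarray):
    """WC84 a, b, c summed over alleles, with per-allele heterozygosities."""
    use = n > 0
    if use.sum() < 2:
        return None
    cc, cn, ch = counts[use], n[use], het_by_allele[use]
    r = len(cn)
    nbar = cn.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - (cn ** 2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    p = cc / (2 * cn[:, None])
    h = ch / cn[:, None]
    pbar = (cn[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = ((cn[:, None] * (p - pbar) ** 2).sum(axis=0)) / ((r - 1) * nbar)
    hbar = (cn[:, None] * h).sum(axis=0) / (r * nbar)
    a = nbar / nc * (s2 - 1.0 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def multilocus_theta(gt: GenotypeTable) -> float:
    """Multilocus Weir-Cockerham theta over all populations."""
    comp = wc_locus_components(gt)
    denom = (comp["a"] + comp["b"] + comp["c"]).sum()
    if denom == 0:
        raise ValueError("zero total variance: all loci monomorphic")
    return float(comp["a"].sum() / denom)


def pairwise_fst(gt: GenotypeTable) -> DistanceMatrix:
    """Pairwise multilocus Weir-Cockerham theta between all population pairs.

    Values are reported untruncated (slightly negative estimates are normal
    for close pairs); use ``.clipped()`` before treating the result as a
    distance.  A pair with no co-typed polymorphic locus is an error.
    """
    pops = gt.population_labels
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    vals = np.zeros((len(pops), len(pops)))
    for i, j in itertools.combinations(range(len(pops)), 2):
        sub = gt.subset_populations([pops[i], pops[j]])
        try:
            theta = multilocus_theta(sub)
        except ValueError:
            raise ValueError(f"no usable locus for pair ({pops[i]}, {pops[j]})")
        vals[i, j] = vals[j, i] = theta
    return DistanceMatrix(pops, vals)


def nei_distance(gt: GenotypeTable) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between populations.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with identities summed over loci:
    Jx = sum_l sum_a p_xla^2 etc.  Pairs with zero shared identity come
    back +inf (masked in the matrix); cap them explicitly before tree
    building.
    """
    pops = gt.population_labels
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    # per pop: concatenated frequency vectors over a common allele basis
    freqs = []
    for locus, lpops, codes, counts, n, _ in _locus_counts(gt):
        with np.errstate(invalid="ignore"):
            p = counts / counts.sum(axis=1, keepdims=True)
        freqs.append(p)
    vals = np.zeros((len(pops), len(pops)))
    mask = np.zeros_like(vals, dtype=bool)
    for i, j in itertools.combinations(range(len(pops)), 2):
        jx = jy = jxy = 0.0
        for p in freqs:
            if not (np.isfinite(p[i]).all() and np.isfinite(p[j]).all()):
                continue
            jx += float((p[i] ** 2).sum())
            jy += float((p[j] ** 2).sum())
            jxy += float((p[i] * p[j]).sum())
        if jxy == 0:
            vals[i, j] = vals[j, i] = np.inf
            mask[i, j] = mask[j, i] = True
        else:
            d = -np.log(jxy / np.sqrt(jx * jy))
            vals[i, j] = vals[j, i] = max(d, 0.0) if abs(d) < 1e-12 else d
    out = np.where(mask, np.nan, vals)
    return DistanceMatrix(pops, out, mask)
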