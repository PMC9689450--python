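"""Independent brute-force / closed-form oracles used only by tests.

These deliberately share no code with the package: sequential-SS ANOVA via
lstsq, full enumeration of allele pairings for the exact HWE p-value, a
straight per-allele transliteration of the Weir-Cockerham theta formulas,
and exhaustive Mantel permutation.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd


def henderson_varcomp(tt: pd.DataFrame, trait: str, year: int):
    """Sequential-SS (Henderson III) moment estimates for balanced designs.

    Fits block; block+provenance; block+provenance+family by OLS and
    converts the sequential sums of squares to variance components via the
    balanced expected mean squares.  Valid only for fully balanced data.
    """
    sub = tt[(tt["trait"] == trait) & (tt["year"] == year)].reset_index(drop=True)
    y = sub["value"].to_numpy(float)

    def dummies(col):
        levels = sorted(sub[col].astype(str).unique())
        M = np.zeros((len(sub), len(levels)))
        for r, v in enumerate(sub[col].astype(str)):
            M[r, levels.index(v)] = 1.0
        return M

    one = np.ones((len(sub), 1))
    Xb = np.hstack([one, dummies("block")])
    Xbp = np.hstack([Xb, dummies("provenance")])
    Xbpf = np.hstack([Xbp, dummies("family")])

    def rss_rank(X):
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), rank

    r0, k0 = rss_rank(Xb)
    r1, k1 = rss_rank(Xbp)
    r2, k2 = rss_rank(Xbpf)
    n = len(sub)
    p = sub["provenance"].nunique()
    f_tot = sub.drop_duplicates(["provenance", "family"]).shape[0]
    n_per_fam = n / f_tot
    n_per_prov = n / p
    ms_p = (r0 - r1) / (k1 - k0)
    ms_f = (r1 - r2) / (k2 - k1)
    ms_e = r2 / (n - k2)
    s2e = ms_e
    s2f = (ms_f - ms_e) / n_per_fam
    s2p = (ms_p - ms_f) / n_per_prov
    return max(s2p, 0.0), max(s2f, 0.0), s2e


def hwe_exact_enumeration(pairs: np.ndarray) -> float:
    """Exact conditional HWE p by enumerating all allele pairings.

    Enumerates every perfect matching of the pooled allele multiset
    (feasible for ~<= 16 alleles), groups matchings by genotype table, and
    sums the probabilities of tables no more probable than the observed one.
    """
    pairs = np.sort(np.asarray(pairs), axis=1)
    alleles = tuple(sorted(pairs.ravel().tolist()))

    def table_key(matching):
        return tuple(sorted(matching))

    tables = Counter()

    def enumerate_matchings(remaining, acc):
        # labeled allele copies: every matching counts, so the per-table
        # tallies are proportional to the conditional HWE probabilities
        if not remaining:
            tables[table_key(acc)] += 1
            return
        a = remaining[0]
        rest = remaining[1:]
        for idx in range(len(rest)):
            b = rest[idx]
            enumerate_matchings(rest[:idx] + rest[idx + 1:],
                                acc + [(min(a, b), max(a, b))])

    enumerate_matchings(list(alleles), [])
    total = sum(tables.values())
    obs_key = table_key([tuple(g) for g in pairs.tolist()])
    obs_prob = tables[obs_key] / total
    p = sum(c for t, c in tables.items() if c / total <= obs_prob + 1e-12) / total
    return p


def wc_theta_direct(pop_genotypes: dict) -> float:
    """Multilocus Weir-Cockerham theta, straight per-allele transliteration.

    ``pop_genotypes`` maps population -> array (n_i, n_loci, 2); missing
    genotypes are (0, 0).  Sums a over alleles and loci divided by the sum
    of a+b+c.
    """
    pops = list(pop_genotypes)
    n_loci = next(iter(pop_genotypes.values())).shape[1]
    num = den = 0.0
    for l in range(n_loci):
        per_pop = {}
        for pop in pops:
            g = pop_genotypes[pop][:, l, :]
            g = g[g[:, 0] != 0]
            if len(g):
                per_pop[pop] = g
        if len(per_pop) < 2:
            continue
        alleles = sorted({int(x) for g in per_pop.values() for x in g.ravel()})
        r = len(per_pop)
        n_i = np.array([len(per_pop[p]) for p in per_pop], float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        for allele in alleles:
            p_i = np.array([np.mean(per_pop[p] == allele) for p in per_pop])
            h_i = np.array([np.mean((per_pop[p][:, 0] != per_pop[p][:, 1])
                                    & ((per_pop[p] == allele).any(axis=1)))
                            for p in per_pop])
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def mantel_exhaustive_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided-positive Mantel p over all relabelings of ``b``."""
    n = a.shape[0]
    il, jl = np.tril_indices(n, k=-1)
    x = a[il, jl]

    def corr(u, v):
        uc, vc = u - u.mean(), v - v.mean()
        return (uc * vc).sum() / math.sqrt((uc ** 2).sum() * (vc ** 2).sum())

    r_obs = corr(x, b[il, jl])
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        perm = np.array(perm)
        r = corr(x, b[np.ix_(perm, perm)][il, jl])
        total += 1
        hits += r >= r_obs - 1e-12
    return hits / total


def nei_identity_distance(freqs_x: list, freqs_y: list) -> float:
    """Nei 1972 D from explicit per-locus identities (independent composition)."""
    jx = sum(float((np.asarray(p) ** 2).sum()) for p in freqs_x)
    jy = sum(float((np.asarray(p) ** 2).sum()) for p in freqs_y)
    jxy = sum(float((np.asarray(px) * np.asarray(py)).sum())
              for px, py in zip(freqs_x, freqs_y))
    return -math.log(jxy / math.sqrt(jx * jy))


def additive_matrix_from_tree(edges: dict, leaves: list) -> np.ndarray:
    """Pairwise path lengths on an explicitly given tree (adjacency dict)."""
    import heapq

    n = len(leaves)
    out = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v, w in edges.get(u, []):
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for j, dst in enumerate(leaves):
            out[i, j] = dist[dst]
    return out
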