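"""Matrix correlation inference: Mantel tests, IBD regression, Q_ST tables.

The Mantel test correlates the lower triangles of two labeled distance
matrices and assesses significance by jointly permuting the rows and
columns of one matrix, which respects the non-independence of pairwise
entries.  Isolation by distance is tested on the linearized scale
x/(1-x) against ln(geographic distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix

__all__ = [
    "MantelResult",
    "IBDRegression",
    "mantel",
    "ibd_regression",
    "correlate_matrices",
    "qst_correlation_table",
    "significance_stars",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: int | None
    n_pairs: int


@dataclass
class IBDRegression:
    """OLS of differentiation/(1-differentiation) on ln distance."""

    a: float  # intercept
    b: float  # slope
    r: float  # Pearson correlation of the transformed pairs
    p: float
    n_pairs: int
    n_excluded: int
    transform: str = "x/(1-x) ~ ln(distance)"


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("constant triangle: correlation undefined")
    return float((xc * yc).sum() / denom)


def mantel(ma: DistanceMatrix, mb: DistanceMatrix, n_perm: int = 10_000,
           seed: int | None = 0, tail: str = "one_sided_positive") -> MantelResult:
    """Mantel test between two labeled matrices.

    ``p = (1 + #{r* >= r}) / (n_perm + 1)`` for the one-sided positive tail
    (the default); the two-sided variant counts ``|r*| >= |r|``.  Rows and
    columns of ``mb`` are permuted jointly.  Masked cells are pairwise
    deleted under every permutation consistently by masking the permuted
    matrix the same way.
    """
    if tail not in ("one_sided_positive", "two_sided"):
        raise ValueError(f"unknown tail: {tail!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if set(ma.labels) != set(mb.labels):
        raise ValueError("label sets differ")
    mb = mb.reorder(ma.labels)
    n = len(ma)
    a_full = ma.values.copy()
    a_full[ma.mask] = np.nan
    b_full = mb.values.copy()
    b_full[mb.mask] = np.nan
    il, jl = np.tril_indices(n, k=-1)
    x, y = a_full[il, jl], b_full[il, jl]
    keep = np.isfinite(x) & np.isfinite(y)
    r_obs = _corr(x[keep], y[keep])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b_full[np.ix_(perm, perm)][il, jl]
        k = np.isfinite(x) & np.isfinite(bp)
        try:
            r_sim = _corr(x[k], bp[k])
        except ValueError:
            continue
        if tail == "one_sided_positive":
            hits += r_sim >= r_obs - 1e-15
        else:
            hits += abs(r_sim) >= abs(r_obs) - 1e-15
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, tail=tail,
                        seed=seed, n_pairs=int(keep.sum()))


def ibd_regression(diff_matrix: DistanceMatrix, geo_matrix: DistanceMatrix,
                   n_perm: int = 10_000, seed: int | None = 0) -> IBDRegression:
    """Isolation-by-distance regression x/(1-x) = a + b ln(d).

    ``diff_matrix`` holds differentiation values (G_ST or theta, < 1);
    ``geo_matrix`` raw distances.  Zero distances (ln undefined) are
    excluded with a count; any differentiation >= 1 is an error because the
    linearization diverges.  The p-value is a two-sided Mantel permutation
    test on the transformed matrices.
    """
    tri = diff_matrix.triangle()
    if np.nanmax(tri) >= 1.0:
        raise ValueError("differentiation >= 1: x/(1-x) linearization undefined")
    lin = diff_matrix.map(lambda v: v / (1.0 - v))
    logd = geo_matrix.map(np.log)  # ln(0) cells masked by map()
    x, y, dropped = DistanceMatrix.paired_triangles(logd, lin)
    if len(x) < 3:
        raise ValueError("fewer than 3 usable pairs")
    b, a = np.polyfit(x, y, 1)
    try:
        r = _corr(x, y)
    except ValueError:
        r = np.nan
    if np.isfinite(r):
        m = mantel(lin, logd, n_perm=n_perm, seed=seed, tail="two_sided")
        p = m.p
    else:
        p = np.nan
    return IBDRegression(a=float(a), b=float(b), r=r, p=p,
                         n_pairs=len(x), n_excluded=dropped)


def correlate_matrices(ma: DistanceMatrix, mb: DistanceMatrix,
                       method: str = "mantel", n_perm: int = 10_000,
                       seed: int | None = 0):
    """Pearson r between two matrices' lower triangles plus a p-value.

    ``method='mantel'`` (default) uses the two-sided permutation test;
    ``'parametric'`` uses the ordinary Pearson p over pairs, which treats
    pairwise entries as independent and is therefore anticonservative.
    Returns ``(r, p, n_pairs)``.
    """
    x, y, _ = DistanceMatrix.paired_triangles(ma, mb)
    r = _corr(x, y)
    if method == "mantel":
        m = mantel(ma, mb, n_perm=n_perm, seed=seed, tail="two_sided")
        return m.r, m.p, m.n_pairs
    if method == "parametric":
        from scipy import stats

        res = stats.pearsonr(x, y)
        return r, float(res.pvalue), len(x)
    raise ValueError(f"unknown method: {method!r}")


def significance_stars(p: float) -> str:
    """ns / * / ** / *** at 0.05, 0.01 and 0.001."""
    if not np.isfinite(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def qst_correlation_table(qst_matrices: dict, predictor_matrices: dict,
                          method: str = "mantel", n_perm: int = 10_000,
                          seed: int | None = 0) -> pd.DataFrame:
    """Correlate every trait-year Q_ST matrix with every predictor matrix.

    ``qst_matrices`` maps (trait, year) -> DistanceMatrix; predictors map
    name -> DistanceMatrix (geographic distance, one climate variable, ...).
    One row per combination with r, p, significance stars and the retained
    pair count (masked Q_ST cells are pairwise-deleted).  p-values are not
    adjusted for multiplicity.
    """
    rows = []
    for (trait, year), qm in sorted(qst_matrices.items()):
        for name, pm in predictor_matrices.items():
            r, p, n_pairs = correlate_matrices(qm, pm, method=method,
                                               n_perm=n_perm, seed=seed)
            rows.append((trait, year, name, r, p, significance_stars(p),
                         n_pairs))
    return pd.DataFrame(rows, columns=["trait", "year", "predictor", "r", "p",
                                       "stars", "n_pairs"])
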