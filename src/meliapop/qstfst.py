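"""Q_ST - F_ST neutrality comparison for half-sib trial traits.

For each trait the observed difference Q_ST - F_ST is compared against a
simulated null distribution of the same statistic under neutrality
(drift only), in the spirit of dam-design Q_ST/F_ST comparison methods:

1. F_ST* per resample: multilocus Weir-Cockerham theta recomputed from a
   bootstrap sample of loci (resampled locus variance components).
2. Neutral variance-component estimates: the analysis-of-variance mean
   squares are drawn from their chi-square sampling distributions --
   MS_P with df_P = n_pops - 1, MS_F with df_F = n_families - n_pops,
   MS_E with the residual df -- around their neutral expectations
   (E[MS_F] = s2_E + k1 s2_F, E[MS_P] = s2_E + k1 s2_F + k2 s2_P0), and
   the components are reconstructed by mean-square subtraction.  Drawing
   at the mean-square level, not the component level, is what propagates
   the estimator's own sampling noise (including negative component
   estimates) into the null.
3. The neutral between-provenance scale s2_P0 is calibrated so that the
   null Q_ST* matches the bootstrap F_ST* in expectation (solved by
   bisection on the drawn sample itself, i.e. with common random numbers),
   which centers the null of Q_ST* - F_ST* at zero by construction.

The observed difference is then located in the null distribution: the
2.5% / 97.5% null quantiles are the critical values, and the two-tailed
p-value is twice the smaller tail fraction (add-one corrected).  A
difference above the upper critical value is called divergent selection,
below the lower one uniform (stabilizing) selection, otherwise drift alone
cannot be rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .markers import GenotypeTable, wc_locus_components
from .quantgen import fit_varcomp, qst_from_varcomp

__all__ = ["QstFstResult", "qst_fst_test", "qstfst_table"]


@dataclass
class QstFstResult:
    trait: str
    year: int
    observed_qst: float
    observed_fst: float
    observed_diff: float
    crit_lo: float
    crit_hi: float
    p_two_tailed: float
    n_resamples: int
    seed: int | None
    direction: str  # uniform | neutral | divergent
    null_mean: float
    converged: bool


def _bootstrap_theta(comp: pd.DataFrame, n_resamples: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Multilocus theta for locus bootstrap samples (vectorized)."""
    a = comp["a"].to_numpy()
    t = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
    L = len(a)
    idx = rng.integers(0, L, size=(n_resamples, L))
    num = a[idx].sum(axis=1)
    den = t[idx].sum(axis=1)
    den[den == 0] = np.nan
    return num / den


def qst_fst_test(tt: pd.DataFrame, gt: GenotypeTable, trait: str, year: int,
                 n_resamples: int = 10_000, seed: int | None = 0) -> QstFstResult:
    """Test one trait-year's Q_ST against the neutral F_ST expectation.

    Requires >= 5 loci and >= 3 populations (the null is too coarse below
    that).  A non-converged trait fit propagates as ``converged=False``.
    """
    if len(gt.loci) < 5:
        raise ValueError("need >= 5 loci for a usable locus bootstrap")
    if len(gt.population_labels) < 3:
        raise ValueError("need >= 3 populations")
    comp = wc_locus_components(gt)
    tot = (comp["a"] + comp["b"] + comp["c"]).sum()
    theta_obs = float(comp["a"].sum() / tot)

    vc = fit_varcomp(tt, trait, year)
    qst_obs = qst_from_varcomp(vc)
    observed = qst_obs - theta_obs

    df_p = vc.n_provenances - 1
    df_f = vc.n_families - vc.n_provenances
    if df_f < 1:
        raise ValueError("fewer families than provenances + 1: family "
                         "component has no degrees of freedom")

    rng = np.random.default_rng(seed)
    theta_star = _bootstrap_theta(comp, n_resamples, rng)
    theta_star = np.where(np.isfinite(theta_star), theta_star, theta_obs)
    df_e = max(vc.n_obs - vc.n_families - len(vc.block_effects), 1)
    x_p = rng.chisquare(df_p, size=n_resamples) / df_p
    x_f = rng.chisquare(df_f, size=n_resamples) / df_f
    x_e = rng.chisquare(df_e, size=n_resamples) / df_e
    s2f = max(vc.sigma2_F, 1e-12 * vc.sigma2_E)
    s2e = vc.sigma2_E
    k1 = vc.n_obs / vc.n_families      # obs per family (balanced EMS coeff)
    k2 = vc.n_obs / vc.n_provenances   # obs per provenance

    # per-resample neutral scale: E[Q_ST] = F_ST* for THAT bootstrap draw,
    # so locus-bootstrap noise cancels in Q_ST* - F_ST* to first order
    theta_plus = np.clip(theta_star, 0.0, 0.99)
    s_base = 8.0 * s2f * theta_plus / (1.0 - theta_plus)

    def draw_null(c):
        ms_e = s2e * x_e
        ms_f = (s2e + k1 * s2f) * x_f
        ms_p = (s2e + k1 * s2f + k2 * c * s_base) * x_p
        comp_f = np.maximum((ms_f - ms_e) / k1, 0.0)
        comp_p = np.maximum((ms_p - ms_f) / k2, 0.0)
        denom = comp_p + 8.0 * comp_f
        tiny = 1e-12 * (s2e + k1 * s2f + 1e-300)
        denom = np.maximum(denom, tiny)
        return comp_p / denom - theta_star

    # the plug-in conditioning is exact only to first order (ratio bias):
    # a single multiplier on the neutral scale recenters the null at zero,
    # solved on the drawn sample itself (common random numbers)
    def mean_gap(log_c):
        return float(draw_null(np.exp(log_c)).mean())

    lo, hi = -12.0, 12.0
    if s_base.max() <= 0 or mean_gap(lo) >= 0:
        null = draw_null(0.0)
    elif mean_gap(hi) <= 0:
        raise RuntimeError("null calibration failed: cannot center the null")
    else:
        c = np.exp(optimize.brentq(mean_gap, lo, hi, xtol=1e-10))
        null = draw_null(c)
    crit_lo, crit_hi = np.percentile(null, [2.5, 97.5])
    ge = int((null >= observed - 1e-15).sum())
    le = int((null <= observed + 1e-15).sum())
    p = min(1.0, 2.0 * (min(ge, le) + 1) / (n_resamples + 1))
    if observed > crit_hi:
        direction = "divergent"
    elif observed < crit_lo:
        direction = "uniform"
    else:
        direction = "neutral"
    return QstFstResult(
        trait=trait, year=year, observed_qst=float(qst_obs),
        observed_fst=theta_obs, observed_diff=float(observed),
        crit_lo=float(crit_lo), crit_hi=float(crit_hi), p_two_tailed=float(p),
        n_resamples=n_resamples, seed=seed, direction=direction,
        null_mean=float(null.mean()), converged=vc.converged,
    )


def _qstfst_stars(p: float) -> str:
    if not np.isfinite(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def qstfst_table(results) -> pd.DataFrame:
    """Report table: one row per trait-year with bounds and stars."""
    results = list(results)
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for r in results:
        rows.append((f"{r.trait}{r.year}", r.observed_diff, r.crit_lo,
                     r.crit_hi, r.p_two_tailed, _qstfst_stars(r.p_two_tailed),
                     r.direction))
    return pd.DataFrame(rows, columns=[
        "trait_code", "qst_minus_fst", "crit_lo_2.5pct", "crit_hi_97.5pct",
        "p_two_tailed", "stars", "direction"])
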