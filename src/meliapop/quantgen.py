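"""REML variance components and Q_ST for half-sib provenance trials.

The observation model for one trait in one year is

    Y_ijkl = mu + B_i + P_j + F_k(j) + E_ijkl

with fixed block effects B_i, random provenance effects P_j ~ N(0, s2_P),
random family-within-provenance effects F_k(j) ~ N(0, s2_F), and residual
E ~ N(0, s2_E).  Because families are open-pollinated half-sibs, the
additive genetic variance within populations is approximately 4 s2_F, and
the trait differentiation index is

    Q_ST = s2_P / (s2_P + 8 s2_F).

Components are estimated by restricted maximum likelihood.  The residual
variance is profiled out and the two variance ratios g_P = s2_P/s2_E and
g_F = s2_F/s2_E are optimized on the log scale with bound constraints, so
estimates are nonnegative by construction and a ratio pinned at the lower
bound is reported as a zero component.  The REML criterion is evaluated
through the random-effect cross-product matrices (Woodbury identity), so a
fit costs O(q^3) per evaluation in the number of random levels q, not in
the number of trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .distmat import DistanceMatrix

__all__ = [
    "VarianceComponents",
    "QstMatrix",
    "validate_trait_table",
    "fit_varcomp",
    "qst_from_varcomp",
    "pairwise_qst",
    "annual_qst_summary",
]

_LOG_RATIO_LO = -20.0  # exp(-20) ~ 2e-9: numerically zero variance ratio
_LOG_RATIO_HI = 12.0


@dataclass
class VarianceComponents:
    """REML estimates for one trait-year fit."""

    sigma2_P: float
    sigma2_F: float
    sigma2_E: float
    block_effects: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    n_provenances: int
    n_families: int

    @property
    def qst(self) -> float:
        return qst_from_varcomp(self)


@dataclass
class QstMatrix:
    """Pairwise Q_ST over provenances for one trait-year.

    Flagged pairs (non-converged fit, or a member with a single family so
    s2_F is weakly identified) are masked in ``matrix``; ``flags`` lists
    them with a reason.
    """

    matrix: DistanceMatrix
    flags: pd.DataFrame
    trait: str
    year: int


def validate_trait_table(tt: pd.DataFrame) -> pd.DataFrame:
    need = {"individual_id", "provenance", "family", "block", "year", "trait",
            "value"}
    missing = need - set(tt.columns)
    if missing:
        raise ValueError(f"trait table is missing columns: {sorted(missing)}")
    dup = tt.duplicated(subset=["individual_id", "trait", "year"])
    if dup.any():
        raise ValueError(
            f"duplicated (individual, trait, year) key at row {int(dup.idxmax())}")
    if not np.isfinite(pd.to_numeric(tt["value"], errors="coerce")).all():
        raise ValueError("non-finite trait values present")
    return tt


def _select(tt: pd.DataFrame, trait: str, year: int) -> pd.DataFrame:
    sub = tt[(tt["trait"] == trait) & (tt["year"] == year)]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}, year {year}")
    return sub.reset_index(drop=True)


def _design(sub: pd.DataFrame, block_levels=None):
    """Fixed design (intercept + block dummies) and random incidence Z_P, Z_F."""
    y = sub["value"].to_numpy(dtype=float)
    n = len(sub)
    if block_levels is None:
        block_levels = sorted(sub["block"].astype(str).unique())
    bl = {b: i for i, b in enumerate(block_levels)}
    X = np.zeros((n, len(block_levels)))
    X[:, 0] = 1.0
    for r, b in enumerate(sub["block"].astype(str)):
        if bl[b] > 0:
            X[r, bl[b]] = 1.0  # treatment coding, first block is baseline
    # drop empty dummy columns (a pair subset may not touch every block)
    keep = X.any(axis=0)
    X = X[:, keep]
    provs = sorted(sub["provenance"].astype(str).unique())
    fams = sorted(sub["family"].astype(str).unique())
    pi = {p: i for i, p in enumerate(provs)}
    fi = {f: i for i, f in enumerate(fams)}
    Zp = np.zeros((n, len(provs)))
    Zf = np.zeros((n, len(fams)))
    for r, (p, f) in enumerate(zip(sub["provenance"].astype(str),
                                   sub["family"].astype(str))):
        Zp[r, pi[p]] = 1.0
        Zf[r, fi[f]] = 1.0
    return y, X, Zp, Zf, provs, fams, [b for b, k in zip(block_levels, keep)]


class _RemlWorkspace:
    """Cross-products for fast repeated REML criterion evaluations."""

    def __init__(self, y, X, Zp, Zf):
        W = np.hstack([Zp, Zf])
        self.qp, self.qf = Zp.shape[1], Zf.shape[1]
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.XtW = X.T @ W
        self.WtW = W.T @ W
        self.Xty = X.T @ y
        self.Wty = W.T @ y
        self.yty = float(y @ y)

    def neg2_reml(self, log_g):
        """Profiled -2 REML log-likelihood (constants dropped) at log ratios."""
        gp, gf = np.exp(log_g)
        ginv = np.concatenate([np.full(self.qp, 1.0 / gp),
                               np.full(self.qf, 1.0 / gf)])
        A = self.WtW + np.diag(ginv)
        try:
            cA = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        logdetA = 2.0 * np.log(np.diag(cA[0])).sum()
        logdetV = logdetA + self.qp * np.log(gp) + self.qf * np.log(gf)
        AiWtX = linalg.cho_solve(cA, self.XtW.T)
        AiWty = linalg.cho_solve(cA, self.Wty)
        XtViX = self.XtX - self.XtW @ AiWtX
        XtViy = self.Xty - self.XtW @ AiWty
        ytViy = self.yty - self.Wty @ AiWty
        try:
            cX = linalg.cho_factor(XtViX, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        beta = linalg.cho_solve(cX, XtViy)
        ypy = ytViy - XtViy @ beta
        dof = self.n - self.p
        if ypy <= 0 or dof <= 0:
            return np.inf, None
        s2e = ypy / dof
        logdetXtViX = 2.0 * np.log(np.diag(cX[0])).sum()
        crit = dof * np.log(s2e) + logdetV + logdetXtViX
        return crit, (s2e, beta)


def fit_varcomp(tt: pd.DataFrame, trait: str, year: int,
                block_levels=None) -> VarianceComponents:
    """REML fit of the block + provenance/family(provenance) model.

    ``block_levels`` fixes the block dummy coding (used by pairwise fits so
    a two-provenance subset keeps the full trial's block structure).  Raises
    on a singular design (single provenance); a fit that fails to converge
    is returned flagged, never silently.
    """
    sub = _select(validate_trait_table(tt), trait, year)
    y, X, Zp, Zf, provs, fams, blocks = _design(sub, block_levels)
    if len(provs) < 2:
        raise ValueError("need >= 2 provenances to separate s2_P")
    if len(fams) < 2:
        raise ValueError("need >= 2 families to separate s2_F")
    if np.var(y) == 0:
        raise ValueError("trait values are constant; variance components "
                         "are undefined")
    ws = _RemlWorkspace(y, X, Zp, Zf)
    bounds = [(_LOG_RATIO_LO, _LOG_RATIO_HI)] * 2
    runs = []
    for start in ([-1.5, -1.5], [0.0, 0.0], [-4.0, -4.0]):
        runs.append(optimize.minimize(lambda t: ws.neg2_reml(t)[0],
                                      np.array(start), method="L-BFGS-B",
                                      bounds=bounds,
                                      options={"ftol": 1e-12, "gtol": 1e-9,
                                               "maxiter": 200}))
    best = min(runs, key=lambda r: r.fun)
    # a boundary fit can end with a flat-line-search "failure" a hair below a
    # cleanly converged start: converged if any successful start matched the
    # pre-polish optimum
    converged = any(r.success and r.fun <= best.fun + 1e-6 * (1 + abs(best.fun))
                    for r in runs)
    # derivative-free polish: the finite-difference L-BFGS-B stop point can
    # sit ~1e-4 (relative) off the optimum, visible against closed forms
    lo, hi = _LOG_RATIO_LO, _LOG_RATIO_HI
    polish = optimize.minimize(
        lambda t: ws.neg2_reml(np.clip(t, lo, hi))[0], best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 500})
    if polish.fun <= best.fun:
        best.x, best.fun = np.clip(polish.x, lo, hi), polish.fun
        converged = converged or bool(polish.success)
    crit, aux = ws.neg2_reml(best.x)
    if aux is None:
        raise RuntimeError("REML criterion undefined at optimum")
    s2e, beta = aux
    gp, gf = np.exp(best.x)
    at_floor = best.x <= _LOG_RATIO_LO + 1e-6
    s2p = 0.0 if at_floor[0] else float(gp * s2e)
    s2f = 0.0 if at_floor[1] else float(gf * s2e)
    block_effects = {b: float(v) for b, v in zip(blocks, beta)}
    return VarianceComponents(
        sigma2_P=s2p, sigma2_F=s2f, sigma2_E=float(s2e),
        block_effects=block_effects, loglik=-0.5 * float(crit),
        converged=bool(converged and np.isfinite(crit)),
        n_obs=len(y), n_provenances=len(provs), n_families=len(fams),
    )


def qst_from_varcomp(vc: VarianceComponents | tuple) -> float:
    """Q_ST = s2_P / (s2_P + 8 s2_F); undefined when both components are 0."""
    if isinstance(vc, VarianceComponents):
        s2p, s2f = vc.sigma2_P, vc.sigma2_F
    else:
        s2p, s2f = vc
    denom = s2p + 8.0 * s2f
    if denom <= 0:
        raise ValueError("Q_ST undefined: s2_P + 8 s2_F = 0")
    return float(s2p / denom)


def pairwise_qst(tt: pd.DataFrame, trait: str, year: int) -> QstMatrix:
    """Refit the model on every provenance pair and apply the Q_ST formula.

    With 22 provenances this yields 231 pairwise values.  Block coding is
    taken from the full table so pair fits share the trial's block
    structure.  Pairs where either member has a single family, or where the
    fit does not converge or leaves Q_ST undefined, are masked and listed
    in ``flags``.
    """
    sub_all = _select(validate_trait_table(tt), trait, year)
    provs = sorted(sub_all["provenance"].astype(str).unique())
    if len(provs) < 2:
        raise ValueError("need >= 2 provenances")
    block_levels = sorted(sub_all["block"].astype(str).unique())
    fam_counts = (sub_all.drop_duplicates(["provenance", "family"])
                  .groupby("provenance").size())
    n = len(provs)
    vals = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    flags = []
    for i, j in itertools.combinations(range(n), 2):
        pair = (provs[i], provs[j])
        pair_tt = sub_all[sub_all["provenance"].isin(pair)]
        reason = None
        if min(fam_counts[pair[0]], fam_counts[pair[1]]) < 2:
            reason = "single_family_member"
        else:
            try:
                vc = fit_varcomp(pair_tt, trait, year, block_levels=block_levels)
                if not vc.converged:
                    reason = "not_converged"
                else:
                    try:
                        vals[i, j] = vals[j, i] = qst_from_varcomp(vc)
                    except ValueError:
                        reason = "qst_undefined"
            except (ValueError, RuntimeError) as exc:
                reason = f"fit_error: {exc}"
        if reason is not None:
            mask[i, j] = mask[j, i] = True
            vals[i, j] = vals[j, i] = np.nan
            flags.append((pair[0], pair[1], reason))
    dm = DistanceMatrix(provs, np.where(mask, np.nan, vals), mask)
    return QstMatrix(matrix=dm, trait=trait, year=year,
                     flags=pd.DataFrame(flags, columns=["prov_a", "prov_b",
                                                        "reason"]))


def annual_qst_summary(tt: pd.DataFrame) -> pd.DataFrame:
    """Per trait-year: phenotypic mean and mean off-diagonal pairwise Q_ST.

    A trait-year whose pairwise matrix is entirely masked (e.g. a constant
    trait) gets NaN mean Q_ST with ``n_pairs = 0`` rather than an error.
    """
    tt = validate_trait_table(tt)
    rows = []
    for (trait, year), grp in tt.groupby(["trait", "year"], sort=True):
        mean_val = float(grp["value"].mean())
        try:
            qm = pairwise_qst(tt, trait, int(year))
            tri = qm.matrix.triangle()
            tri = tri[np.isfinite(tri)]
            mean_qst = float(tri.mean()) if len(tri) else np.nan
            n_pairs = int(len(tri))
        except ValueError:
            mean_qst, n_pairs = np.nan, 0
        rows.append((trait, int(year), mean_val, mean_qst, n_pairs))
    return pd.DataFrame(rows, columns=["trait", "year", "trait_mean",
                                       "mean_pairwise_qst", "n_pairs"])
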