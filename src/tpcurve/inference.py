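"""Grouped Wald chi-square tests and per-group polynomial trend contrasts.

Wald tests are Type-II (marginality-respecting): each grouped term is tested
after all other terms except those containing it, via hypothesis matrices
orthogonalized against the containing terms in the metric of the coefficient
covariance.  On balanced designs this coincides with Type III, and the
statistics are invariant to the factor coding used in the fit.

Trend contrasts report, per embryogenesis level, the linear/quadratic/cubic
orthogonal-basis trends (fertilization levels averaged with equal weights)
and the three pairwise contrasts with Tukey-adjusted p-values (studentized
range for k means, asymptotic df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate, linalg, stats

from .glmm_fit import GLMMFit, TERM_FACTORS, TERM_ORDER

__all__ = ["WaldResult", "TrendSet", "wald_tests", "trend_contrasts", "tukey_pvalue"]

_TREND_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}


@dataclass(frozen=True)
class WaldResult:
    term: str
    chi2: float
    df: int
    p: float


@dataclass
class TrendSet:
    """Per-group trend estimates and Tukey-adjusted pairwise contrasts."""

    trends: pd.DataFrame     # embryo_temp, trend, estimate, se
    contrasts: pd.DataFrame  # pair, trend, estimate, se, z, p_unadjusted, p_tukey


def _relatives(term: str) -> list[str]:
    fac = TERM_FACTORS[term]
    return [t for t in TERM_ORDER if t != term and fac < TERM_FACTORS[t]]


def _type2_L(term: str, term_cols: dict, V: np.ndarray) -> np.ndarray:
    """Hypothesis matrix for a Type-II grouped Wald test.

    Rows span the part of the term's coefficient subspace conjugate
    (V-orthogonal) to the subspace of its higher-order relatives.
    """
    p = V.shape[0]
    I = np.eye(p)
    rel_cols = [c for t in _relatives(term) for c in term_cols[t]]
    own_cols = list(term_cols[term])
    Zo = I[:, own_cols]
    if rel_cols:
        # V-orthogonalize the term's own coefficient directions against the
        # containing terms; the result spans exactly |own_cols| dimensions
        # because distinct coordinate directions stay independent
        Xr = I[:, rel_cols]
        G = Xr.T @ V @ Xr
        Q = Zo - Xr @ linalg.solve(G, Xr.T @ V @ Zo)
    else:
        Q = Zo
    return Q.T


def wald_tests(fit: GLMMFit) -> list[WaldResult]:
    """Type-II grouped Wald chi-square tests for the seven model terms."""
    V = fit.vcov_beta
    b = fit.beta
    out = []
    for term in TERM_ORDER:
        L = _type2_L(term, fit.term_cols, V)
        Lb = L @ b
        M = L @ V @ L.T
        try:
            chi2 = float(Lb @ linalg.solve(M, Lb, assume_a="pos"))
            df = L.shape[0]
        except linalg.LinAlgError:
            warnings.warn(f"singular contrast covariance for term {term!r}; using pseudo-inverse")
            Mp = np.linalg.pinv(M)
            chi2 = float(Lb @ Mp @ Lb)
            df = int(np.linalg.matrix_rank(M))
        chi2 = max(chi2, 0.0)
        out.append(WaldResult(term=term, chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df))))
    return out


def _range_cdf(q: float, k: int) -> float:
    """P(range of k iid standard normals < q); exact infinite-df Tukey reference."""
    if q <= 0:
        return 0.0
    f = lambda x: stats.norm.pdf(x) * (stats.norm.cdf(x) - stats.norm.cdf(x - q)) ** (k - 1)
    val, _ = integrate.quad(f, -np.inf, np.inf, limit=200)
    return min(1.0, k * val)


def tukey_pvalue(z: float, k: int = 3) -> float:
    """Tukey-adjusted two-sided p for a pairwise z among k means (infinite df)."""
    return 1.0 - _range_cdf(np.sqrt(2.0) * abs(z), k)


def trend_contrasts(fit: GLMMFit) -> TrendSet:
    """Trend estimates per embryogenesis level and Tukey-adjusted contrasts."""
    if len(fit.embryo_levels) < 2:
        raise ValueError("need at least 2 embryogenesis levels")
    V = fit.vcov_beta
    b = fit.beta
    k = len(fit.embryo_levels)

    # linear functionals: rows of the group coefficient map for degrees 1..3
    funcs: dict[tuple[float, int], np.ndarray] = {}
    for e in fit.embryo_levels:
        M = fit.group_coeff_map(e)
        for d in range(1, fit.spec.degree + 1):
            funcs[(e, d)] = M[d]

    trends = []
    for e in fit.embryo_levels:
        for d in range(1, fit.spec.degree + 1):
            c = funcs[(e, d)]
            trends.append({
                "embryo_temp": e,
                "trend": _TREND_NAMES.get(d, f"deg{d}"),
                "estimate": float(c @ b),
                "se": float(np.sqrt(c @ V @ c)),
            })

    contrasts = []
    for e1, e2 in combinations(fit.embryo_levels, 2):
        for d in range(1, fit.spec.degree + 1):
            c = funcs[(e1, d)] - funcs[(e2, d)]
            est = float(c @ b)
            se = float(np.sqrt(c @ V @ c))
            z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            p_un = float(2 * stats.norm.sf(abs(z)))
            contrasts.append({
                "pair": f"{e1:g}v{e2:g}",
                "trend": _TREND_NAMES.get(d, f"deg{d}"),
                "estimate": est,
                "se": se,
                "z": float(z),
                "p_unadjusted": p_un,
                "p_tukey": float(max(tukey_pvalue(z, k=k), p_un)),
            })
    return TrendSet(trends=pd.DataFrame(trends), contrasts=pd.DataFrame(contrasts))
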