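"""Unconditional parametric bootstrap of the fitted mixed model.

Each replicate redraws block and vial intercepts from the fitted variance
components, simulates binomial outcomes over the original design rows,
refits the full model, and re-extracts the curve descriptors for every
embryogenesis group.  Percentile 95% CIs are reported per group x
descriptor, together with replicate-wise pairwise group differences and the
two significance rules: non-overlap of group CIs (conservative) and
exclusion of zero by the difference CI.

Replicate r draws its RNG from a child seed of (seed, r), so the draws
matrix is invariant to execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from .descriptors import CENSORED, DESCRIPTOR_NAMES, extract_descriptors
from .glmm_fit import GLMMFit, _fit_glmm_state, _FitState

__all__ = ["BootstrapResult", "parametric_bootstrap", "compare_descriptors"]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Replicate descriptor draws plus percentile summaries."""

    B: int
    seed: int
    groups: tuple[float, ...]
    descriptors: tuple[str, ...]
    draws: np.ndarray            # (B_ok, n_groups, n_desc); censored -> NaN
    censored: np.ndarray         # boolean mask, same shape
    n_failed: int
    point_estimates: pd.DataFrame   # plug-in descriptors of the base fit
    summary: pd.DataFrame           # group, descriptor, mean, ci_lo, ci_hi, n_eff
    pairwise: pd.DataFrame          # pair, descriptor, mean, ci_lo, ci_hi, n_eff

    def to_dict(self) -> dict:
        return {
            "B": self.B, "seed": self.seed,
            "groups": list(self.groups), "descriptors": list(self.descriptors),
            "draws": np.where(np.isnan(self.draws), None, self.draws).tolist(),
            "censored": self.censored.tolist(),
            "n_failed": self.n_failed,
            "point_estimates": self.point_estimates.to_dict(orient="list"),
            "summary": self.summary.to_dict(orient="list"),
            "pairwise": self.pairwise.to_dict(orient="list"),
        }


def _summarize(draws: np.ndarray, groups, desc_names) -> pd.DataFrame:
    rows = []
    for gi, g in enumerate(groups):
        for di, dn in enumerate(desc_names):
            col = draws[:, gi, di]
            ok = col[~np.isnan(col)]
            if len(ok) == 0:
                rows.append({"group": g, "descriptor": dn, "mean": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan, "n_eff": 0})
                continue
            lo, hi = np.percentile(ok, [2.5, 97.5])
            rows.append({"group": g, "descriptor": dn, "mean": float(np.mean(ok)),
                         "ci_lo": float(lo), "ci_hi": float(hi), "n_eff": int(len(ok))})
    return pd.DataFrame(rows)


def _pairwise(draws: np.ndarray, groups, desc_names) -> pd.DataFrame:
    rows = []
    for (i, g1), (j, g2) in combinations(enumerate(groups), 2):
        for di, dn in enumerate(desc_names):
            d1, d2 = draws[:, i, di], draws[:, j, di]
            mask = ~np.isnan(d1) & ~np.isnan(d2)   # pairwise-complete
            diff = d1[mask] - d2[mask]
            if len(diff) == 0:
                rows.append({"pair": f"{g1:g}-{g2:g}", "descriptor": dn,
                             "mean": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "n_eff": 0})
                continue
            lo, hi = np.percentile(diff, [2.5, 97.5])
            rows.append({"pair": f"{g1:g}-{g2:g}", "descriptor": dn,
                         "mean": float(np.mean(diff)), "ci_lo": float(lo),
                         "ci_hi": float(hi), "n_eff": int(len(diff))})
    return pd.DataFrame(rows)


def parametric_bootstrap(
    fit: GLMMFit,
    B: int = 1000,
    seed: int = 0,
    search_range: tuple[float, float] | None = None,
    breadth_fraction: float = 0.5,
    limit_fraction: float = 0.05,
    extrapolation_margin: float = 10.0,
    max_failure_fraction: float = 0.1,
) -> BootstrapResult:
    """Bootstrap descriptor draws and percentile CIs from a converged fit."""
    if not fit.converged:
        raise RuntimeError(f"base fit did not converge: {fit.message}")
    state: _FitState | None = fit._state
    if state is None:
        raise RuntimeError("fit carries no design state; refit from the data table")

    X, Zb, trials = state.X, state.Zb, state.trials
    n, nb = Zb.shape[0], Zb.shape[1]
    eta_fix = X @ fit.beta
    bidx = np.argmax(Zb, axis=1)
    groups = tuple(fit.embryo_levels)
    desc_names = DESCRIPTOR_NAMES
    kw = dict(search_range=search_range, breadth_fraction=breadth_fraction,
              limit_fraction=limit_fraction, extrapolation_margin=extrapolation_margin)

    draws = np.full((B, len(groups), len(desc_names)), np.nan)
    cens = np.zeros_like(draws, dtype=bool)
    ok_rows = []
    n_failed = 0
    base_theta = np.log([max(fit.sigma_block, 1e-6), max(fit.sigma_vial, 1e-6)])
    # warm starts always come from the base fit (stored immutably on the fit
    # artifact) so repeated calls and any execution order give identical draws
    base_d = None if fit._d_hat is None else fit._d_hat.copy()
    for r in range(B):
        state.d_hat = None if base_d is None else base_d.copy()
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        u_b = rng.normal(0.0, fit.sigma_block, size=nb)
        u_v = rng.normal(0.0, fit.sigma_vial, size=n)
        p = expit(eta_fix + u_b[bidx] + u_v)
        succ = rng.binomial(state.trials.astype(int), p).astype(float)
        try:
            refit = _fit_glmm_state(state, succ, x0=base_theta.copy(), maxiter=30, fast=True)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        for gi, g in enumerate(groups):
            d = extract_descriptors(refit, g, **kw)
            dd = d.as_dict()
            for di, dn in enumerate(desc_names):
                if d.flags.get(dn) == CENSORED or (
                    dn == "Tbr" and d.flags.get("Tbr") == CENSORED
                ):
                    cens[r, gi, di] = True
                    draws[r, gi, di] = np.nan
                else:
                    draws[r, gi, di] = dd[dn]
        ok_rows.append(r)
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge "
            f"(limit {max_failure_fraction:.0%})"
        )
    draws = draws[ok_rows]
    cens = cens[ok_rows]

    pe_rows = []
    for g in groups:
        d = extract_descriptors(fit, g, **kw)
        row = {"group": g, **{k: d.as_dict()[k] for k in desc_names}}
        pe_rows.append(row)
    point = pd.DataFrame(pe_rows)

    return BootstrapResult(
        B=B, seed=seed, groups=groups, descriptors=desc_names,
        draws=draws, censored=cens, n_failed=n_failed,
        point_estimates=point,
        summary=_summarize(draws, groups, desc_names),
        pairwise=_pairwise(draws, groups, desc_names),
    )


def compare_descriptors(result: BootstrapResult) -> pd.DataFrame:
    """Both significance rules for every descriptor and group pair.

    Rule (a): the two groups' 95% CIs do not overlap (conservative).
    Rule (b): the 95% CI of the replicate-wise difference excludes 0; a
    closed interval containing 0 (including the degenerate [0, 0]) counts as
    non-significant.
    """
    if len(result.groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    s = result.summary.set_index(["group", "descriptor"])
    rows = []
    for _, prow in result.pairwise.iterrows():
        g1s, g2s = prow["pair"].split("-")
        g1, g2 = float(g1s), float(g2s)
        dn = prow["descriptor"]
        ci1 = s.loc[(g1, dn)]
        ci2 = s.loc[(g2, dn)]
        overlap_sig = bool(ci1["ci_lo"] > ci2["ci_hi"] or ci2["ci_lo"] > ci1["ci_hi"])
        diff_sig = bool(prow["ci_lo"] > 0 or prow["ci_hi"] < 0)
        rows.append({
            "pair": prow["pair"], "descriptor": dn,
            "diff_mean": prow["mean"], "diff_ci_lo": prow["ci_lo"], "diff_ci_hi": prow["ci_hi"],
            "ci_overlap_significant": overlap_sig,
            "diff_ci_significant": diff_sig,
        })
    return pd.DataFrame(rows)
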