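"""Curve prediction and descriptor extraction (Pmax, Topt, Tbr, CTmin, CTmax).

Descriptors are functionals of the population-level curve for one
embryogenesis group: random effects at 0 on the logit scale, fertilization
levels averaged on the logit scale with equal weights.  Because the inverse
logit is strictly increasing, the optimum and all threshold crossings are
computed on the cubic logit polynomial directly: stationary points from the
derivative's quadratic formula, crossings by monotone-segment bisection
refined to 1e-9 degC.  Fractions of peak are taken on the probability scale
(f * Pmax), and crossings may be followed beyond the search range up to an
extrapolation margin; such values are flagged ``extrapolated``.  If a curve
turns back (local minimum above the threshold) or the margin is exhausted
before crossing, the value is set to the search limit and flagged
``censored``.  A brute-force grid oracle with the same definitions is
provided for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .glmm_fit import GLMMFit
from .poly_basis import basis_raw_coeffs

__all__ = [
    "CurveDescriptors",
    "predict_curve",
    "group_logit_poly",
    "extract_descriptors",
    "grid_descriptors",
    "descriptors_from_poly",
    "grid_descriptors_from_poly",
    "DESCRIPTOR_NAMES",
]

DESCRIPTOR_NAMES = ("Pmax", "Topt", "Tbr", "CTmin", "CTmax")

INTERIOR = "interior"
BOUNDARY = "boundary"
EXTRAPOLATED = "extrapolated"
CENSORED = "censored"


@dataclass
class CurveDescriptors:
    """Descriptors of one group's thermal performance curve.

    ``flags`` maps descriptor name (including Tbr_lo/Tbr_hi) to one of
    interior / boundary / extrapolated / censored.
    """

    group: float
    Pmax: float
    Topt: float
    Tbr: float
    Tbr_lo: float
    Tbr_hi: float
    CTmin: float
    CTmax: float
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def thermal_tolerance(self) -> float:
        """Derived convenience: CTmax - CTmin."""
        return self.CTmax - self.CTmin

    def as_dict(self) -> dict:
        return {
            "group": self.group, "Pmax": self.Pmax, "Topt": self.Topt,
            "Tbr": self.Tbr, "Tbr_lo": self.Tbr_lo, "Tbr_hi": self.Tbr_hi,
            "CTmin": self.CTmin, "CTmax": self.CTmax, "flags": dict(self.flags),
        }

    def check_ordering(self) -> None:
        ok = lambda name: self.flags.get(name) in (INTERIOR, BOUNDARY, EXTRAPOLATED)
        seq = []
        if ok("CTmin"):
            seq.append(self.CTmin)
        if ok("Tbr_lo"):
            seq.append(self.Tbr_lo)
        seq.append(self.Topt)
        if ok("Tbr_hi"):
            seq.append(self.Tbr_hi)
        if ok("CTmax"):
            seq.append(self.CTmax)
        if any(a > b + 1e-9 for a, b in zip(seq, seq[1:])):
            raise AssertionError(f"descriptor ordering violated: {seq}")


def group_logit_poly(fit: GLMMFit, embryo_temp: float) -> np.ndarray:
    """Ascending raw coefficients (length degree+1) of the group's logit curve."""
    if embryo_temp not in fit.embryo_levels:
        raise ValueError(f"unknown embryogenesis level {embryo_temp!r}")
    w = fit.group_coeff_map(embryo_temp) @ fit.beta  # coeffs on [const, basis cols]
    raw = basis_raw_coeffs(fit.basis)                # (degree, degree+1)
    coeffs = np.zeros(fit.spec.degree + 1)
    coeffs[0] = w[0]
    for d in range(1, fit.spec.degree + 1):
        coeffs += w[d] * raw[d - 1]
    return coeffs


def predict_curve(fit: GLMMFit, embryo_temp: float, temps) -> np.ndarray:
    """Population-level survival probabilities for one embryogenesis group."""
    coeffs = group_logit_poly(fit, embryo_temp)
    t = np.asarray(temps, dtype=float)
    return expit(np.polynomial.polynomial.polyval(t, coeffs))


# --------------------------------------------------------------------------
# analytic extraction on a cubic


def _polyval(c, t):
    return np.polynomial.polynomial.polyval(t, c)


def _stationary_points(coeffs: np.ndarray) -> np.ndarray:
    der = np.polynomial.polynomial.polyder(coeffs)
    # drop numerically-negligible leading coefficients: a ~1e-18 cubic term
    # would otherwise wreck the conditioning of the companion matrix
    scale = np.max(np.abs(der)) if der.size else 0.0
    if scale == 0.0:
        return np.array([])
    der = np.polynomial.polynomial.polytrim(der, tol=1e-12 * scale)
    if len(der) < 2:
        return np.array([])
    roots = np.polynomial.polynomial.polyroots(der)
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real)


def _argmax_on_range(coeffs, lo, hi):
    cands = [lo, hi] + [float(s) for s in _stationary_points(coeffs) if lo < s < hi]
    vals = [_polyval(coeffs, t) for t in cands]
    best = max(vals)
    # tie-breaking: smallest temperature wins
    topt = min(t for t, v in zip(cands, vals) if v >= best - 1e-12)
    flag = BOUNDARY if (abs(topt - lo) < 1e-12 or abs(topt - hi) < 1e-12) else INTERIOR
    return topt, flag


def _side_crossing(coeffs, topt, y, lo, hi, limit, direction):
    """Nearest threshold crossing on one side of the optimum.

    Walks monotone segments (delimited by stationary points) outward from
    ``topt`` to ``limit``; a crossing is refined by bisection.  Returns
    (value, flag).  ``direction`` is +1 (upper) or -1 (lower); ``lo``/``hi``
    bound the search range used for the extrapolation flag.
    """
    g = lambda t: _polyval(coeffs, t) - y
    if g(topt) <= 0:
        # peak itself at/below threshold: crossing degenerate at topt
        return topt, INTERIOR if lo <= topt <= hi else EXTRAPOLATED
    stats_pts = [float(s) for s in _stationary_points(coeffs)]
    if direction > 0:
        pts = sorted([s for s in stats_pts if topt < s < limit])
        nodes = [topt] + pts + [limit]
    else:
        pts = sorted([s for s in stats_pts if limit < s < topt], reverse=True)
        nodes = [topt] + pts + [limit]
    for a, b in zip(nodes, nodes[1:]):
        ga, gb = g(a), g(b)
        if gb > ga + 1e-12:
            # curve rises moving outward: turned back above the threshold
            return float(limit), CENSORED
        if gb <= 0:
            x = brentq(g, min(a, b), max(a, b), xtol=1e-12, rtol=8.9e-16)
            flag = INTERIOR if lo - 1e-12 <= x <= hi + 1e-12 else EXTRAPOLATED
            return float(x), flag
    # margin exhausted while still above the threshold
    return float(limit), CENSORED


def descriptors_from_poly(
    coeffs,
    group: float = np.nan,
    search_range: tuple[float, float] = (10.0, 28.0),
    breadth_fraction: float = 0.5,
    limit_fraction: float = 0.05,
    extrapolation_margin: float = 10.0,
) -> CurveDescriptors:
    """Analytic descriptor extraction from a logit-scale cubic."""
    if not (0 < limit_fraction < breadth_fraction < 1):
        raise ValueError("need 0 < limit_fraction < breadth_fraction < 1")
    coeffs = np.asarray(coeffs, dtype=float)
    lo, hi = search_range
    if lo >= hi:
        raise ValueError("search_range must be increasing")
    topt, topt_flag = _argmax_on_range(coeffs, lo, hi)
    eta_max = _polyval(coeffs, topt)
    pmax = float(expit(eta_max))
    flags = {"Topt": topt_flag, "Pmax": topt_flag}
    vals = {}
    for frac, (nm_lo, nm_hi) in ((breadth_fraction, ("Tbr_lo", "Tbr_hi")),
                                 (limit_fraction, ("CTmin", "CTmax"))):
        y = float(logit(frac * pmax))
        v_lo, f_lo = _side_crossing(coeffs, topt, y, lo, hi, lo - extrapolation_margin, -1)
        v_hi, f_hi = _side_crossing(coeffs, topt, y, lo, hi, hi + extrapolation_margin, +1)
        vals[nm_lo], flags[nm_lo] = v_lo, f_lo
        vals[nm_hi], flags[nm_hi] = v_hi, f_hi
    flags["Tbr"] = (CENSORED if CENSORED in (flags["Tbr_lo"], flags["Tbr_hi"])
                    else (EXTRAPOLATED if EXTRAPOLATED in (flags["Tbr_lo"], flags["Tbr_hi"])
                          else INTERIOR))
    desc = CurveDescriptors(
        group=group, Pmax=pmax, Topt=float(topt),
        Tbr=float(vals["Tbr_hi"] - vals["Tbr_lo"]),
        Tbr_lo=float(vals["Tbr_lo"]), Tbr_hi=float(vals["Tbr_hi"]),
        CTmin=float(vals["CTmin"]), CTmax=float(vals["CTmax"]), flags=flags,
    )
    desc.check_ordering()
    return desc


def extract_descriptors(
    fit: GLMMFit,
    embryo_temp: float,
    search_range: tuple[float, float] | None = None,
    breadth_fraction: float = 0.5,
    limit_fraction: float = 0.05,
    extrapolation_margin: float = 10.0,
) -> CurveDescriptors:
    """Descriptors for one embryogenesis group of a fitted model."""
    if search_range is None:
        t = fit.basis.construction_temps
        search_range = (min(t), max(t))
    coeffs = group_logit_poly(fit, embryo_temp)
    return descriptors_from_poly(
        coeffs, group=embryo_temp, search_range=search_range,
        breadth_fraction=breadth_fraction, limit_fraction=limit_fraction,
        extrapolation_margin=extrapolation_margin,
    )


# --------------------------------------------------------------------------
# brute-force grid oracle


def grid_descriptors_from_poly(
    coeffs,
    group: float = np.nan,
    search_range: tuple[float, float] = (10.0, 28.0),
    breadth_fraction: float = 0.5,
    limit_fraction: float = 0.05,
    extrapolation_margin: float = 10.0,
    step: float = 0.001,
) -> CurveDescriptors:
    """Same definitions evaluated on a dense grid (testing oracle only)."""
    if not (0 < limit_fraction < breadth_fraction < 1):
        raise ValueError("need 0 < limit_fraction < breadth_fraction < 1")
    coeffs = np.asarray(coeffs, dtype=float)
    lo, hi = search_range
    grid = np.arange(lo, hi + step / 2, step)
    eta = _polyval(coeffs, grid)
    # first-hit tie-breaking: smallest temperature among near-maximal points
    near = np.nonzero(eta >= eta.max() - 1e-12)[0]
    i_max = int(near[0])
    topt = float(grid[i_max])
    topt_flag = BOUNDARY if i_max in (0, len(grid) - 1) else INTERIOR
    pmax = float(expit(eta[i_max]))
    flags = {"Topt": topt_flag, "Pmax": topt_flag}
    vals = {}

    lo_ext = np.arange(lo - extrapolation_margin, lo, step)
    hi_ext = np.arange(hi + step, hi + extrapolation_margin + step / 2, step)
    full = np.concatenate([lo_ext, grid, hi_ext])
    eta_full = _polyval(coeffs, full)
    j_max = i_max + len(lo_ext)

    def walk(y, direction):
        j = j_max
        prev = eta_full[j]
        while True:
            j += direction
            if j < 0 or j >= len(full):
                limit = full[0] if direction < 0 else full[-1]
                return float(limit), CENSORED
            e = eta_full[j]
            if e < y:
                x = float(full[j])
                flag = INTERIOR if lo - 1e-9 <= x <= hi + 1e-9 else EXTRAPOLATED
                return x, flag
            if e > prev + 1e-12:
                # turned back above threshold
                limit = lo - extrapolation_margin if direction < 0 else hi + extrapolation_margin
                return float(limit), CENSORED
            prev = e

    for frac, (nm_lo, nm_hi) in ((breadth_fraction, ("Tbr_lo", "Tbr_hi")),
                                 (limit_fraction, ("CTmin", "CTmax"))):
        y = float(logit(frac * pmax))
        vals[nm_lo], flags[nm_lo] = walk(y, -1)
        vals[nm_hi], flags[nm_hi] = walk(y, +1)
    flags["Tbr"] = (CENSORED if CENSORED in (flags["Tbr_lo"], flags["Tbr_hi"])
                    else (EXTRAPOLATED if EXTRAPOLATED in (flags["Tbr_lo"], flags["Tbr_hi"])
                          else INTERIOR))
    return CurveDescriptors(
        group=group, Pmax=pmax, Topt=topt,
        Tbr=float(vals["Tbr_hi"] - vals["Tbr_lo"]),
        Tbr_lo=float(vals["Tbr_lo"]), Tbr_hi=float(vals["Tbr_hi"]),
        CTmin=float(vals["CTmin"]), CTmax=float(vals["CTmax"]), flags=flags,
    )


def grid_descriptors(
    fit: GLMMFit,
    embryo_temp: float,
    search_range: tuple[float, float] | None = None,
    breadth_fraction: float = 0.5,
    limit_fraction: float = 0.05,
    extrapolation_margin: float = 10.0,
    step: float = 0.001,
) -> CurveDescriptors:
    if search_range is None:
        t = fit.basis.construction_temps
        search_range = (min(t), max(t))
    coeffs = group_logit_poly(fit, embryo_temp)
    return grid_descriptors_from_poly(
        coeffs, group=embryo_temp, search_range=search_range,
        breadth_fraction=breadth_fraction, limit_fraction=limit_fraction,
        extrapolation_margin=extrapolation_margin, step=step,
    )
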