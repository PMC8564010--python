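import numpy as np
import pytest
from scipy.special import expit, logit

import tpcurve as tp
from tpcurve.descriptors import (
    BOUNDARY,
    CENSORED,
    EXTRAPOLATED,
    INTERIOR,
    descriptors_from_poly,
    grid_descriptors_from_poly,
    group_logit_poly,
    predict_curve,
)

from conftest import make_fit_from_poly


def quad_poly(peak_logit=2.0, topt=19.0, quad=-0.05):
    """Ascending coefficients of peak_logit + quad * (T - topt)^2."""
    return np.array([
        peak_logit + quad * topt**2,
        -2 * quad * topt,
        quad,
        0.0,
    ])


def analytic_quad_descriptors(peak_logit=2.0, topt=19.0, quad=-0.05):
    """Independent closed-form oracle for the symmetric quadratic case."""
    pmax = expit(peak_logit)
    out = {"Topt": topt, "Pmax": pmax}
    for frac, (lo_nm, hi_nm) in ((0.5, ("Tbr_lo", "Tbr_hi")), (0.05, ("CTmin", "CTmax"))):
        y = logit(frac * pmax)
        half = np.sqrt((y - peak_logit) / quad)
        out[lo_nm], out[hi_nm] = topt - half, topt + half
    out["Tbr"] = out["Tbr_hi"] - out["Tbr_lo"]
    return out


def test_closed_form_symmetric_quadratic():
    d = descriptors_from_poly(quad_poly())
    oracle = analytic_quad_descriptors()
    assert d.Topt == pytest.approx(19.0, abs=1e-9)
    assert d.Pmax == pytest.approx(oracle["Pmax"], abs=1e-9)
    for k in ("Tbr_lo", "Tbr_hi", "CTmin", "CTmax", "Tbr"):
        assert getattr(d, k) == pytest.approx(oracle[k], abs=1e-6), k
    # frozen reference values
    assert d.Pmax == pytest.approx(0.8808, abs=1e-4)
    assert d.CTmin == pytest.approx(8.922, abs=0.01)
    assert d.CTmax == pytest.approx(29.078, abs=0.01)
    assert d.Tbr == pytest.approx(13.385, abs=0.01)
    assert d.flags["CTmin"] == EXTRAPOLATED       # below the 10 degC range edge
    assert d.flags["Tbr_lo"] == INTERIOR


def test_thresholds_hit_stated_fractions_of_peak():
    coeffs = quad_poly()
    d = descriptors_from_poly(coeffs)
    eta = lambda t: np.polynomial.polynomial.polyval(t, coeffs)
    assert expit(eta(d.Topt)) == pytest.approx(d.Pmax, abs=1e-8)
    for t in (d.Tbr_lo, d.Tbr_hi):
        assert expit(eta(t)) == pytest.approx(0.5 * d.Pmax, abs=1e-8)
    for t in (d.CTmin, d.CTmax):
        assert expit(eta(t)) == pytest.approx(0.05 * d.Pmax, abs=1e-8)


def test_monotone_curve_boundary_and_censoring():
    d = descriptors_from_poly([0.0, 0.2, 0.0, 0.0])
    assert d.Topt == 28.0
    assert d.flags["Topt"] == BOUNDARY
    assert d.flags["CTmax"] == CENSORED
    assert d.CTmax == 38.0   # set to the search limit


def test_flat_curve_tie_breaks_to_smallest_temperature():
    d = descriptors_from_poly([0.5, 0.0, 0.0, 0.0])
    g = grid_descriptors_from_poly([0.5, 0.0, 0.0, 0.0])
    assert d.Topt == 10.0 and g.Topt == 10.0
    assert d.flags["Topt"] == BOUNDARY
    for nm in ("Tbr_lo", "Tbr_hi", "CTmin", "CTmax"):
        assert d.flags[nm] == CENSORED


def test_turn_back_censoring():
    """A cubic that dips toward the threshold, turns back up, and never
    crosses on the right is censored there."""
    # eta = 2 - 0.05 (T-19)^2 + 0.004 (T-19)^3: local min right of the peak
    base = quad_poly()
    skew = np.polynomial.polynomial.polymul(
        [(-19.0) ** 3, 3 * 19.0**2, -3 * 19.0, 1.0], [0.004]
    )
    coeffs = base + np.pad(skew, (0, 4 - len(skew)))[:4]
    d = descriptors_from_poly(coeffs)
    g = grid_descriptors_from_poly(coeffs)
    assert d.flags["CTmax"] == g.flags["CTmax"]
    assert d.flags["Tbr_hi"] == g.flags["Tbr_hi"]


def random_cubics(n, seed):
    """Random logit-scale cubics with a peak somewhere near the assay range."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        peak = rng.uniform(0.2, 3.5)
        topt = rng.uniform(12.0, 26.0)
        quad = -rng.uniform(0.01, 0.2)
        cubic = rng.uniform(-0.008, 0.008)
        c = topt
        coeffs = np.array([
            peak + quad * c * c - cubic * c**3,
            -2 * quad * c + 3 * cubic * c * c,
            quad - 3 * cubic * c,
            cubic,
        ])
        out.append(coeffs)
    return out


@pytest.mark.parametrize("seed", [0, 1])
def test_analytic_matches_grid_oracle(seed):
    for coeffs in random_cubics(50, seed):
        a = descriptors_from_poly(coeffs)
        g = grid_descriptors_from_poly(coeffs, step=0.001)
        assert a.flags["Topt"] == g.flags["Topt"], coeffs
        assert abs(a.Topt - g.Topt) <= 0.01
        assert abs(a.Pmax - g.Pmax) <= 1e-6
        for nm in ("Tbr_lo", "Tbr_hi", "CTmin", "CTmax"):
            fa, fg = a.flags[nm], g.flags[nm]
            assert (fa == CENSORED) == (fg == CENSORED), (coeffs, nm)
            if fa != CENSORED:
                assert abs(getattr(a, nm) - getattr(g, nm)) <= 0.01, (coeffs, nm)


def test_shift_equivariance_and_pmax_invariance():
    coeffs = quad_poly()
    delta = 2.5
    # shift the polynomial along the temperature axis: p(T - delta)
    shifted = np.zeros(4)
    from math import comb

    for k, c in enumerate(coeffs):
        for j in range(k + 1):
            shifted[j] += c * comb(k, j) * (-delta) ** (k - j)
    d0 = descriptors_from_poly(coeffs, search_range=(5.0, 33.0))
    d1 = descriptors_from_poly(shifted, search_range=(7.5, 35.5))
    assert d1.Topt == pytest.approx(d0.Topt + delta, abs=1e-6)
    assert d1.CTmin == pytest.approx(d0.CTmin + delta, abs=1e-6)
    assert d1.CTmax == pytest.approx(d0.CTmax + delta, abs=1e-6)
    assert d1.Tbr == pytest.approx(d0.Tbr, abs=1e-6)
    assert d1.Pmax == pytest.approx(d0.Pmax, abs=1e-12)


def test_breadth_fraction_ordering():
    for coeffs in random_cubics(20, 3):
        d50 = descriptors_from_poly(coeffs, breadth_fraction=0.5)
        d80 = descriptors_from_poly(coeffs, breadth_fraction=0.8)
        if CENSORED in (d50.flags["Tbr"], d80.flags["Tbr"]):
            continue
        assert d80.Tbr < d50.Tbr


def test_fraction_validation():
    with pytest.raises(ValueError):
        descriptors_from_poly(quad_poly(), breadth_fraction=1.2)
    with pytest.raises(ValueError):
        descriptors_from_poly(quad_poly(), limit_fraction=0.6, breadth_fraction=0.5)


def test_ordering_invariant():
    for coeffs in random_cubics(40, 7):
        descriptors_from_poly(coeffs).check_ordering()   # raises on violation


# ---------------------------------------------------------------------------
# fit-level prediction


def test_predict_curve_zero_beta_gives_half():
    fit = make_fit_from_poly([0.0, 0.0, 0.0, 0.0])
    probs = predict_curve(fit, 18.0, np.linspace(10, 28, 50))
    assert np.allclose(probs, 0.5, atol=1e-12)


def test_predict_curve_known_polynomial():
    fit = make_fit_from_poly(quad_poly())
    assert predict_curve(fit, 20.0, [19.0])[0] == pytest.approx(expit(2.0), abs=1e-9)
    d = tp.extract_descriptors(fit, 18.0)
    assert d.Topt == pytest.approx(19.0, abs=1e-9)


def test_predict_curve_unknown_group(small_fit):
    with pytest.raises(ValueError, match="unknown"):
        predict_curve(small_fit, 25.0, [20.0])


def test_prediction_coding_invariance(small_table):
    f1 = tp.fit_glmm(small_table, tp.ModelSpec(coding="treatment"))
    f2 = tp.fit_glmm(small_table, tp.ModelSpec(coding="sum"))
    grid = np.linspace(10, 28, 37)
    for e in f1.embryo_levels:
        p1 = predict_curve(f1, e, grid)
        p2 = predict_curve(f2, e, grid)
        assert np.allclose(p1, p2, atol=1e-6)


def test_extract_matches_grid_on_fit(small_fit):
    for e in small_fit.embryo_levels:
        a = tp.extract_descriptors(small_fit, e)
        g = tp.grid_descriptors(small_fit, e)
        assert abs(a.Topt - g.Topt) <= 0.01
        assert abs(a.Pmax - g.Pmax) <= 1e-6


def test_group_logit_poly_is_fert_average(small_fit):
    coeffs = group_logit_poly(small_fit, 20.0)
    grid = np.linspace(10, 28, 19)
    eta_avg = np.zeros_like(grid)
    for f in small_fit.fert_levels:
        M = small_fit.cell_coeff_map(f, 20.0)
        w = M @ small_fit.beta
        from tpcurve.poly_basis import evaluate_basis

        eta_avg += w[0] + evaluate_basis(small_fit.basis, grid) @ w[1:]
    eta_avg /= len(small_fit.fert_levels)
    assert np.allclose(
        np.polynomial.polynomial.polyval(grid, coeffs), eta_avg, atol=1e-8
    )
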