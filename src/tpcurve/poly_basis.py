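"""Orthogonal polynomial basis in assay temperature.

Builds a degree-``d`` orthogonal polynomial basis on an observation-level
temperature vector via the Forsythe three-term recurrence, and evaluates the
same polynomials at arbitrary new temperatures from the stored recurrence
constants alone.  Columns are orthogonal to the constant and to each other,
and have unit (weighted) sum of squares on the construction vector, matching
the convention of standard statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PolyBasis", "build_basis", "evaluate_basis", "basis_raw_coeffs"]


@dataclass(frozen=True)
class PolyBasis:
    """Recurrence constants of an orthogonal polynomial basis.

    The monic orthogonal polynomials satisfy

        p_0(x) = 1,
        p_1(x) = x - alpha_0,
        p_{k+1}(x) = (x - alpha_k) p_k(x) - beta_k p_{k-1}(x),

    with inner product <f, g> = sum_i w_i f(x_i) g(x_i) over the construction
    vector.  Returned basis columns are p_k / norm_k for k = 1..degree.
    """

    degree: int
    alphas: tuple[float, ...]
    betas: tuple[float, ...]   # betas[0] unused (set to 0)
    norms: tuple[float, ...]   # sqrt(<p_k, p_k>) for k = 0..degree
    construction_temps: tuple[float, ...]
    construction_weights: tuple[float, ...]

    def evaluate(self, new_temps: np.ndarray) -> np.ndarray:
        return evaluate_basis(self, new_temps)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "alphas": list(self.alphas),
            "betas": list(self.betas),
            "norms": list(self.norms),
            "construction_temps": list(self.construction_temps),
            "construction_weights": list(self.construction_weights),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolyBasis":
        return cls(
            degree=int(d["degree"]),
            alphas=tuple(d["alphas"]),
            betas=tuple(d["betas"]),
            norms=tuple(d["norms"]),
            construction_temps=tuple(d["construction_temps"]),
            construction_weights=tuple(d["construction_weights"]),
        )


def build_basis(temps, degree: int = 3, weights=None) -> PolyBasis:
    """Construct the orthogonal basis on a temperature vector.

    Parameters
    ----------
    temps
        Observation-level temperatures (duplicates encode replicate
        weighting), or unique temperatures combined with ``weights``.
    degree
        Polynomial degree; requires at least ``degree + 1`` distinct values.
    weights
        Optional positive counts/weights per entry of ``temps``.
    """
    x = np.asarray(temps, dtype=float).ravel()
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != x.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match temps in length")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(np.unique(x)) < degree + 1:
        raise ValueError(
            f"rank error: need >= {degree + 1} distinct temperatures, "
            f"got {len(np.unique(x))}"
        )
    # collapse duplicates so the recurrence sums run over unique support
    xu, inv = np.unique(x, return_inverse=True)
    wu = np.bincount(inv, weights=w)

    alphas, betas, norms = [], [0.0], []
    p_prev = np.zeros_like(xu)
    p_cur = np.ones_like(xu)
    sq_cur = float(np.sum(wu))            # <p_0, p_0>
    norms.append(np.sqrt(sq_cur))
    span_sq = (np.max(xu) - np.min(xu)) ** 2 + 1.0
    for k in range(degree):
        alpha = float(np.sum(wu * xu * p_cur**2) / sq_cur)
        p_next = (xu - alpha) * p_cur - (betas[k] * p_prev if k > 0 else 0.0)
        sq_next = float(np.sum(wu * p_next**2))
        if sq_next <= 1e-12 * sq_cur * span_sq:
            raise ValueError("rank error: temperatures do not support requested degree")
        alphas.append(alpha)
        betas.append(sq_next / sq_cur)
        norms.append(np.sqrt(sq_next))
        p_prev, p_cur, sq_cur = p_cur, p_next, sq_next
    return PolyBasis(
        degree=degree,
        alphas=tuple(alphas),
        betas=tuple(betas[:degree]),
        norms=tuple(norms),
        construction_temps=tuple(xu.tolist()),
        construction_weights=tuple(wu.tolist()),
    )


def evaluate_basis(basis: PolyBasis, new_temps) -> np.ndarray:
    """Evaluate the basis polynomials at new temperatures.

    Returns an ``(len(new_temps), degree)`` matrix whose columns are the
    normalized basis polynomials; evaluating at the construction vector
    reproduces the training design matrix.
    """
    x = np.asarray(new_temps, dtype=float).ravel()
    out = np.empty((x.size, basis.degree))
    p_prev = np.zeros_like(x)
    p_cur = np.ones_like(x)
    for k in range(basis.degree):
        p_next = (x - basis.alphas[k]) * p_cur - (basis.betas[k] * p_prev if k > 0 else 0.0)
        out[:, k] = p_next / basis.norms[k + 1]
        p_prev, p_cur = p_cur, p_next
    return out


def basis_raw_coeffs(basis: PolyBasis) -> np.ndarray:
    """Exact raw-monomial coefficients of each normalized basis column.

    Returns a ``(degree, degree + 1)`` array; row ``k`` holds ascending
    coefficients (c0..c_degree) of basis column ``k + 1`` as an ordinary
    polynomial in temperature.  Exact because each column is a polynomial of
    degree <= ``degree``: interpolate on degree+1 nodes.
    """
    lo = min(basis.construction_temps)
    hi = max(basis.construction_temps)
    nodes = np.linspace(lo, hi, basis.degree + 1)
    vals = evaluate_basis(basis, nodes)          # (degree+1, degree)
    V = np.vander(nodes, basis.degree + 1, increasing=True)
    return np.linalg.solve(V, vals).T
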