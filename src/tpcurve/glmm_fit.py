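"""Binomial logit mixed model fitted by Laplace-approximated maximum likelihood.

Fixed effects: full factorial of the degree-3 orthogonal temperature trend
with the fertilization and embryogenesis factors (all lower-order terms
included).  Random effects: intercepts for block and for vial nested in
block.  The marginal likelihood is approximated by the Laplace method: an
inner penalized IRLS solves jointly for the fixed coefficients and the
conditional modes of the (spherically scaled) random effects given the
variance parameters; an outer bounded quasi-Newton optimizes the two
log-SDs.

Rows are aggregated to vial-level binomial counts before fitting — all
individuals in a vial share covariates and random effects, so the likelihood
is unchanged and fits are much faster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit, gammaln

from .data_model import SurvivalTable
from .poly_basis import PolyBasis, build_basis, evaluate_basis

__all__ = ["ModelSpec", "GLMMFit", "fit_glmm", "fit_glm", "SeparationError"]

logger = logging.getLogger(__name__)

#: order of grouped fixed-effect terms (beyond the intercept)
TERM_ORDER = (
    "fert",
    "embryo",
    "fert:embryo",
    "trend",
    "fert:trend",
    "embryo:trend",
    "fert:embryo:trend",
)

#: factor content of each term, used for containment (Type-II relatives)
TERM_FACTORS = {
    "fert": frozenset({"F"}),
    "embryo": frozenset({"E"}),
    "fert:embryo": frozenset({"F", "E"}),
    "trend": frozenset({"T"}),
    "fert:trend": frozenset({"F", "T"}),
    "embryo:trend": frozenset({"E", "T"}),
    "fert:embryo:trend": frozenset({"F", "E", "T"}),
}


class SeparationError(RuntimeError):
    """Complete separation: a treatment cell has all-0 or all-1 outcomes."""


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the fitted model.

    degree
        Polynomial degree of the temperature trend (default 3).
    coding
        Factor coding for the two treatment factors: ``"treatment"``
        (dummy, lowest temperature as reference) or ``"sum"``.  All reported
        quantities are coding-invariant.
    """

    degree: int = 3
    coding: str = "treatment"

    def __post_init__(self):
        if self.coding not in ("treatment", "sum"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def n_fixed(self, n_fert: int, n_embryo: int) -> int:
        return (self.degree + 1) * n_fert * n_embryo

    def to_dict(self) -> dict:
        return {"degree": self.degree, "coding": self.coding}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(degree=int(d["degree"]), coding=str(d["coding"]))


# --------------------------------------------------------------------------
# design-matrix construction


def _factor_columns(values: np.ndarray, levels: Sequence[float], coding: str) -> np.ndarray:
    """(n, len(levels)-1) coding matrix for one categorical factor."""
    n = len(values)
    k = len(levels)
    out = np.zeros((n, k - 1))
    for j, lev in enumerate(levels[1:]):
        out[:, j] = values == lev
    if coding == "sum":
        # sum coding: level i -> e_i (i<k-1), last level -> -1 everywhere
        out = np.zeros((n, k - 1))
        for j, lev in enumerate(levels[:-1]):
            out[:, j] = values == lev
        out[values == levels[-1], :] = -1.0
    return out


def _model_matrix(agg: pd.DataFrame, basis: PolyBasis, spec: ModelSpec,
                  fert_levels, embryo_levels):
    """Build the fixed-effect matrix with term-grouped column blocks.

    Returns (X, names, term_cols, col_map) where ``term_cols`` maps term
    name -> column indices and ``col_map`` maps (factor_cell_column,
    basis_degree) -> column index.  Factor-cell columns are ordered
    [1, F..., E..., F:E...]; basis degree 0 is the constant.
    """
    P = evaluate_basis(basis, agg["assay_temp"].to_numpy())  # (n, degree)
    Df = _factor_columns(agg["fert_temp"].to_numpy(), fert_levels, spec.coding)
    De = _factor_columns(agg["embryo_temp"].to_numpy(), embryo_levels, spec.coding)
    n = len(agg)

    factor_blocks: list[tuple[str, np.ndarray]] = [("1", np.ones((n, 1)))]
    factor_blocks.append(("F", Df))
    factor_blocks.append(("E", De))
    fe = np.stack([Df[:, i] * De[:, j] for i in range(Df.shape[1]) for j in range(De.shape[1])], axis=1)
    factor_blocks.append(("F:E", fe))

    # term name for (factor block, with/without trend)
    term_of = {("1", 0): "intercept", ("F", 0): "fert", ("E", 0): "embryo", ("F:E", 0): "fert:embryo",
               ("1", 1): "trend", ("F", 1): "fert:trend", ("E", 1): "embryo:trend",
               ("F:E", 1): "fert:embryo:trend"}

    cols: list[np.ndarray] = []
    names: list[str] = []
    term_cols: dict[str, list[int]] = {}
    col_map: dict[tuple[int, int], int] = {}
    flat_factor_cols: list[tuple[str, int, np.ndarray]] = []
    for bname, block in factor_blocks:
        for j in range(block.shape[1]):
            flat_factor_cols.append((bname, j, block[:, j]))

    # ordering: all degree-0 columns by term, then trend blocks by term
    for with_trend in (0, 1):
        for bname, block in factor_blocks:
            term = term_of[(bname, with_trend)]
            for j in range(block.shape[1]):
                fc_idx = next(
                    i for i, (bn, jj, _) in enumerate(flat_factor_cols)
                    if bn == bname and jj == j
                )
                if with_trend == 0:
                    cols.append(block[:, j][:, None])
                    names.append(f"{bname}[{j}]" if bname != "1" else "(Intercept)")
                    term_cols.setdefault(term, []).append(len(names) - 1)
                    col_map[(fc_idx, 0)] = len(names) - 1
                else:
                    for d in range(1, spec.degree + 1):
                        cols.append((block[:, j] * P[:, d - 1])[:, None])
                        nm = f"poly{d}" if bname == "1" else f"{bname}[{j}]:poly{d}"
                        names.append(nm)
                        term_cols.setdefault(term, []).append(len(names) - 1)
                        col_map[(fc_idx, d)] = len(names) - 1
    X = np.hstack(cols)
    return X, names, {k: tuple(v) for k, v in term_cols.items()}, col_map


def _factor_cell_row(fert: float, embryo: float, fert_levels, embryo_levels, coding: str) -> np.ndarray:
    """Row vector over the factor-cell columns [1, F..., E..., F:E...] for one cell."""
    df = _factor_columns(np.array([fert]), fert_levels, coding)[0]
    de = _factor_columns(np.array([embryo]), embryo_levels, coding)[0]
    fe = np.array([df[i] * de[j] for i in range(len(df)) for j in range(len(de))])
    return np.concatenate([[1.0], df, de, fe])


# --------------------------------------------------------------------------
# fit artifact


@dataclass
class GLMMFit:
    """Result of a (mixed or fixed-only) binomial fit."""

    beta: np.ndarray
    beta_names: list[str]
    vcov_beta: np.ndarray
    sigma_block: float
    sigma_vial: float
    loglik: float
    converged: bool
    message: str
    basis: PolyBasis
    spec: ModelSpec
    fert_levels: tuple[float, ...]
    embryo_levels: tuple[float, ...]
    term_cols: dict[str, tuple[int, ...]]
    col_map: dict[tuple[int, int], int]
    boundary_flags: dict[str, bool] = field(default_factory=dict)
    re_modes: dict[str, dict[str, float]] = field(default_factory=dict)
    n_obs: int = 0
    _state: "._FitState | None" = field(default=None, repr=False)
    _d_hat: "np.ndarray | None" = field(default=None, repr=False)

    def cell_coeff_map(self, fert: float, embryo: float) -> np.ndarray:
        """(degree+1, p) matrix M with M @ beta = the cell's coefficients on
        [constant, basis_1 .. basis_degree]."""
        a = _factor_cell_row(fert, embryo, self.fert_levels, self.embryo_levels, self.spec.coding)
        p = len(self.beta)
        M = np.zeros((self.spec.degree + 1, p))
        for d in range(self.spec.degree + 1):
            for fc_idx, w in enumerate(a):
                if w != 0.0:
                    M[d, self.col_map[(fc_idx, d)]] += w
        return M

    def group_coeff_map(self, embryo: float) -> np.ndarray:
        """Cell map averaged over fertilization levels with equal weights."""
        maps = [self.cell_coeff_map(f, embryo) for f in self.fert_levels]
        return np.mean(maps, axis=0)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "beta_names": list(self.beta_names),
            "vcov_beta": self.vcov_beta.tolist(),
            "sigma_block": self.sigma_block,
            "sigma_vial": self.sigma_vial,
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "message": self.message,
            "basis": self.basis.to_dict(),
            "spec": self.spec.to_dict(),
            "fert_levels": list(self.fert_levels),
            "embryo_levels": list(self.embryo_levels),
            "term_cols": {k: list(v) for k, v in self.term_cols.items()},
            "col_map": {f"{i},{d}": c for (i, d), c in self.col_map.items()},
            "boundary_flags": self.boundary_flags,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLMMFit":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            beta_names=list(d["beta_names"]),
            vcov_beta=np.asarray(d["vcov_beta"], dtype=float),
            sigma_block=float(d["sigma_block"]),
            sigma_vial=float(d["sigma_vial"]),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            message=str(d["message"]),
            basis=PolyBasis.from_dict(d["basis"]),
            spec=ModelSpec.from_dict(d["spec"]),
            fert_levels=tuple(d["fert_levels"]),
            embryo_levels=tuple(d["embryo_levels"]),
            term_cols={k: tuple(v) for k, v in d["term_cols"].items()},
            col_map={(int(k.split(",")[0]), int(k.split(",")[1])): int(v)
                     for k, v in d["col_map"].items()},
            boundary_flags=dict(d.get("boundary_flags", {})),
            n_obs=int(d.get("n_obs", 0)),
        )


@dataclass
class _FitState:
    """Internal fitting state reused by bootstrap refits (same design, new y)."""

    X: np.ndarray
    Zb: np.ndarray            # (n_vials, n_blocks) one-hot
    bidx: np.ndarray          # block index per vial row
    trials: np.ndarray
    agg: pd.DataFrame
    basis: PolyBasis
    spec: ModelSpec
    fert_levels: tuple[float, ...]
    embryo_levels: tuple[float, ...]
    names: list[str]
    term_cols: dict[str, tuple[int, ...]]
    col_map: dict[tuple[int, int], int]
    theta_hat: np.ndarray | None = None
    d_hat: np.ndarray | None = None


# --------------------------------------------------------------------------
# core numerics
#
# The penalized system has arrow structure: the block design is one-hot (so
# Zb' W Zb is diagonal) and the vial design is the identity (so its block is
# diagonal too).  Solving by Schur complement on the diagonal vial block
# reduces the dense factorization from (p + n_blocks + n_vials)^2 to
# (p + n_blocks)^2, and the Laplace log-determinant to O(n) plus a diagonal
# block determinant.

_ETA_CLIP = 30.0


def _eta_of(X, bidx, sb, sv, d):
    p = X.shape[1]
    nb = int(bidx.max()) + 1
    return X @ d[:p] + sb * d[p:p + nb][bidx] + sv * d[p + nb:]


def _pen_dev(eta, d, succ, trials, p):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    dev = -2.0 * np.sum(succ * np.log(mu) + (trials - succ) * np.log1p(-mu))
    u = d[p:]
    return dev + u @ u


def _weights_z(eta, succ, trials):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    W = np.maximum(trials * mu * (1 - mu), 1e-10)
    z = eta + (succ - trials * mu) / W
    return W, z


def _schur_solve(X, Zb, bidx, W, sb, sv, z):
    """One penalized weighted least-squares solve via the arrow structure.

    Returns (d, cho_factor_of_S) where S is the Schur complement onto the
    (beta, block) coordinates."""
    p, nb = X.shape[1], Zb.shape[1]
    XtW = X.T * W
    A11 = np.empty((p + nb, p + nb))
    A11[:p, :p] = XtW @ X
    XtWZb = XtW @ Zb
    A11[:p, p:] = sb * XtWZb
    A11[p:, :p] = A11[:p, p:].T
    bW = np.bincount(bidx, weights=W, minlength=nb)
    A11[p:, p:] = np.diag(sb * sb * bW + 1.0)
    A12 = np.vstack([sv * XtW, sb * sv * (Zb.T * W)])
    Dv = sv * sv * W + 1.0
    b1 = np.concatenate([XtW @ z, sb * (Zb.T @ (W * z))])
    b2 = sv * W * z
    A12_D = A12 / Dv
    S = A11 - A12_D @ A12.T
    cf = linalg.cho_factor(S, lower=True, check_finite=False)
    x1 = linalg.cho_solve(cf, b1 - A12_D @ b2, check_finite=False)
    x2 = (b2 - A12.T @ x1) / Dv
    return np.concatenate([x1, x2]), cf


def _pirls(X, Zb, bidx, succ, trials, sb, sv, d0=None, tol=1e-10, maxit=80):
    """Penalized IRLS for (beta, u) jointly; spherical unit penalty on u.

    Returns (d, W, pen_dev, converged)."""
    n, p = X.shape
    nb = Zb.shape[1]
    m = p + nb + n
    d = np.zeros(m) if d0 is None else d0.copy()
    eta = _eta_of(X, bidx, sb, sv, d)
    dev = _pen_dev(eta, d, succ, trials, p)
    converged = False
    W = None
    for _ in range(maxit):
        W, z = _weights_z(eta, succ, trials)
        try:
            d_new, _ = _schur_solve(X, Zb, bidx, W, sb, sv, z)
        except linalg.LinAlgError:
            break
        # step-halving on the penalized deviance
        step = d_new - d
        eta_new = _eta_of(X, bidx, sb, sv, d_new)
        new_dev = _pen_dev(eta_new, d_new, succ, trials, p)
        halvings = 0
        while new_dev > dev + 1e-9 and halvings < 12:
            step *= 0.5
            d_new = d + step
            eta_new = _eta_of(X, bidx, sb, sv, d_new)
            new_dev = _pen_dev(eta_new, d_new, succ, trials, p)
            halvings += 1
        rel = abs(dev - new_dev) / (abs(new_dev) + 0.1)
        d, dev, eta = d_new, new_dev, eta_new
        if rel < tol:
            converged = True
            break
    W, _ = _weights_z(eta, succ, trials)
    return d, W, dev, converged


def _laplace_logdet(bidx, W, sb, sv, nb):
    Dv = sv * sv * W + 1.0
    bW = np.bincount(bidx, weights=W, minlength=nb)
    cW = np.bincount(bidx, weights=W * W / Dv, minlength=nb)
    diag_b = sb * sb * bW + 1.0 - sb * sb * sv * sv * cW
    return float(np.sum(np.log(Dv)) + np.sum(np.log(diag_b)))


def _laplace_crit(theta_log, state: _FitState, succ, warm, pirls_tol=1e-10):
    """-2 * Laplace log marginal likelihood (up to the binomial constant)."""
    sb, sv = np.exp(theta_log)
    X, Zb, bidx, trials = state.X, state.Zb, state.bidx, state.trials
    d, W, pen_dev, ok = _pirls(X, Zb, bidx, succ, trials, sb, sv,
                               d0=warm.get("d"), tol=pirls_tol)
    if warm.get("d") is not None and not ok:
        # poisoned warm start (e.g. after the optimizer probed an extreme
        # theta): restart cold and keep the better solution
        d2, W2, pen_dev2, _ = _pirls(X, Zb, bidx, succ, trials, sb, sv,
                                     d0=None, tol=pirls_tol)
        if pen_dev2 < pen_dev:
            d, W, pen_dev = d2, W2, pen_dev2
    warm["d"] = d
    logdet = _laplace_logdet(bidx, W, sb, sv, Zb.shape[1])
    return pen_dev + logdet, d, W


def _vcov_beta_at(state: _FitState, W, sb, sv):
    """Covariance of beta: top-left block of the inverse penalized Hessian
    (variance parameters held fixed), i.e. the inverse Schur complement."""
    X, Zb, bidx = state.X, state.Zb, state.bidx
    p, nb = X.shape[1], Zb.shape[1]
    XtW = X.T * W
    A11 = np.empty((p + nb, p + nb))
    A11[:p, :p] = XtW @ X
    XtWZb = XtW @ Zb
    A11[:p, p:] = sb * XtWZb
    A11[p:, :p] = A11[:p, p:].T
    bW = np.bincount(bidx, weights=W, minlength=nb)
    A11[p:, p:] = np.diag(sb * sb * bW + 1.0)
    A12 = np.vstack([sv * XtW, sb * sv * (Zb.T * W)])
    Dv = sv * sv * W + 1.0
    S = A11 - (A12 / Dv) @ A12.T
    try:
        Sinv = linalg.inv(S)
    except linalg.LinAlgError:
        Sinv = np.linalg.pinv(S)
    V = Sinv[:p, :p]
    return 0.5 * (V + V.T)


def _irls_glm(X, succ, trials, tol=1e-12, maxit=100):
    """Plain binomial IRLS (no random effects).  Returns (beta, W, dev, ok)."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    dev = _pen_dev(eta, beta, succ, trials, p)
    converged = False
    W = None
    for _ in range(maxit):
        W, z = _weights_z(eta, succ, trials)
        XtW = X.T * W
        try:
            beta_new = linalg.solve(XtW @ X, XtW @ z, assume_a="pos", check_finite=False)
        except linalg.LinAlgError:
            beta_new = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)[0]
        step = beta_new - beta
        new_dev = _pen_dev(X @ beta_new, beta_new, succ, trials, p)
        halvings = 0
        while new_dev > dev + 1e-9 and halvings < 12:
            step *= 0.5
            beta_new = beta + step
            new_dev = _pen_dev(X @ beta_new, beta_new, succ, trials, p)
            halvings += 1
        rel = abs(dev - new_dev) / (abs(new_dev) + 0.1)
        beta, dev = beta_new, new_dev
        eta = X @ beta
        if rel < tol:
            converged = True
            break
    W, _ = _weights_z(eta, succ, trials)
    return beta, W, dev, converged


def _check_separation(agg: pd.DataFrame) -> str | None:
    for (f, e), grp in agg.groupby(["fert_temp", "embryo_temp"], sort=True):
        s, m = grp["successes"].sum(), grp["trials"].sum()
        if s == 0 or s == m:
            return (f"complete separation: cell (fert={f}, embryo={e}) has "
                    f"{'all-0' if s == 0 else 'all-1'} outcomes")
    return None


def _aggregate(table: SurvivalTable) -> pd.DataFrame:
    df = table.to_frame()
    agg = (
        df.groupby(["block", "vial", "fert_temp", "embryo_temp", "assay_temp"], sort=True)["outcome"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    return agg


def _prepare_state(table: SurvivalTable, spec: ModelSpec) -> tuple[_FitState, np.ndarray]:
    table.validate(min_distinct_temps=spec.degree + 1)
    agg = _aggregate(table)
    fert_levels = tuple(sorted(set(agg["fert_temp"])))
    embryo_levels = tuple(sorted(set(agg["embryo_temp"])))
    # basis on the observation-level temperature vector (trials as weights)
    basis = build_basis(agg["assay_temp"].to_numpy(), degree=spec.degree,
                        weights=agg["trials"].to_numpy())
    X, names, term_cols, col_map = _model_matrix(agg, basis, spec, fert_levels, embryo_levels)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name aliased columns via QR pivoting
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        aliased = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"rank-deficient fixed-effect design; aliased terms: {aliased}")
    blocks = sorted(set(agg["block"]))
    bidx = agg["block"].map({b: i for i, b in enumerate(blocks)}).to_numpy()
    Zb = np.zeros((len(agg), len(blocks)))
    Zb[np.arange(len(agg)), bidx] = 1.0
    state = _FitState(
        X=X, Zb=Zb, bidx=bidx.astype(int), trials=agg["trials"].to_numpy(dtype=float), agg=agg,
        basis=basis, spec=spec, fert_levels=fert_levels, embryo_levels=embryo_levels,
        names=names, term_cols=term_cols, col_map=col_map,
    )
    return state, agg["successes"].to_numpy(dtype=float)


def _binom_const(succ, trials) -> float:
    return float(np.sum(gammaln(trials + 1) - gammaln(succ + 1) - gammaln(trials - succ + 1)))


LOG_SD_LOWER = -12.0
LOG_SD_UPPER = 2.5


def _fit_glmm_state(state: _FitState, succ: np.ndarray, x0=None,
                    maxiter: int = 60, fast: bool = False) -> GLMMFit:
    n, p = state.X.shape
    sep_msg = _check_separation(state.agg)

    warm: dict = {}
    if state.d_hat is not None and len(state.d_hat) == p + state.Zb.shape[1] + n:
        warm["d"] = state.d_hat

    pirls_tol = 1e-9 if fast else 1e-10
    opts = ({"maxiter": maxiter, "ftol": 1e-9, "gtol": 5e-4, "eps": 1e-4}
            if fast else
            {"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-5, "eps": 1e-5})

    def objective(x):
        crit, _, _ = _laplace_crit(x, state, succ, warm, pirls_tol=pirls_tol)
        return crit

    if x0 is None:
        x0 = np.log([0.1, 0.1])
    x0 = np.clip(x0, LOG_SD_LOWER + 1e-6, LOG_SD_UPPER - 1e-6)
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(LOG_SD_LOWER, LOG_SD_UPPER)] * 2,
        options=opts,
    )
    crit, d, W = _laplace_crit(res.x, state, succ, warm, pirls_tol=pirls_tol)
    sb, sv = np.exp(res.x)
    vcov = _vcov_beta_at(state, W, sb, sv)
    beta = d[:p]
    nb = state.Zb.shape[1]
    blocks = sorted(set(state.agg["block"]))
    re_modes = {
        "block": {b: float(sb * d[p + i]) for i, b in enumerate(blocks)},
        "vial": {
            f"{row.block}:{row.vial}": float(sv * d[p + nb + i])
            for i, row in enumerate(state.agg.itertuples(index=False))
        },
    }
    loglik = _binom_const(succ, state.trials) - 0.5 * crit
    # an SD estimated below ~exp(-6) is a boundary (effectively zero) fit
    boundary = {"sigma_block": bool(res.x[0] <= -6.0),
                "sigma_vial": bool(res.x[1] <= -6.0)}
    converged = bool(res.success or res.status == 0)
    message = str(res.message)
    if sep_msg is not None:
        converged = False
        message = sep_msg
    state.theta_hat = res.x.copy()
    state.d_hat = d.copy()
    return GLMMFit(
        beta=beta, beta_names=list(state.names), vcov_beta=vcov,
        sigma_block=float(sb), sigma_vial=float(sv), loglik=float(loglik),
        converged=converged, message=message, basis=state.basis, spec=state.spec,
        fert_levels=state.fert_levels, embryo_levels=state.embryo_levels,
        term_cols=state.term_cols, col_map=state.col_map,
        boundary_flags=boundary, re_modes=re_modes,
        n_obs=int(state.trials.sum()), _state=state, _d_hat=d.copy(),
    )


def fit_glmm(table: SurvivalTable, spec: ModelSpec | None = None) -> GLMMFit:
    """Fit the binomial mixed model by Laplace-approximated ML.

    Deterministic given the data: starting values come from the fixed-only
    GLM and SDs start at 0.1.  Boundary fits (an SD driven to ~0) are
    reported with ``boundary_flags`` rather than failing.  Complete
    separation in a treatment cell is flagged as non-convergence.
    """
    spec = spec or ModelSpec()
    state, succ = _prepare_state(table, spec)
    return _fit_glmm_state(state, succ)


def fit_glm(table: SurvivalTable, spec: ModelSpec | None = None) -> GLMMFit:
    """Fixed-effects-only binomial fit (plain IRLS); SDs fixed at 0.

    Serves as the degenerate-case oracle for :func:`fit_glmm` and as a fast
    fallback.  Returns the same artifact type.
    """
    spec = spec or ModelSpec()
    state, succ = _prepare_state(table, spec)
    sep_msg = _check_separation(state.agg)
    X, trials = state.X, state.trials
    n, p = X.shape
    d, W, dev, converged = _irls_glm(X, succ, trials)
    A = (X.T * W) @ X
    try:
        vcov = linalg.inv(A)
    except linalg.LinAlgError:
        vcov = np.linalg.pinv(A)
    loglik = _binom_const(succ, trials) - 0.5 * dev
    message = "IRLS converged" if converged else "IRLS did not converge"
    if sep_msg is not None:
        converged = False
        message = sep_msg
    return GLMMFit(
        beta=d, beta_names=list(state.names), vcov_beta=0.5 * (vcov + vcov.T),
        sigma_block=0.0, sigma_vial=0.0, loglik=float(loglik),
        converged=bool(converged), message=message, basis=state.basis, spec=spec,
        fert_levels=state.fert_levels, embryo_levels=state.embryo_levels,
        term_cols=state.term_cols, col_map=state.col_map,
        boundary_flags={"sigma_block": True, "sigma_vial": True},
        re_modes={}, n_obs=int(trials.sum()), _state=state,
    )
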