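"""Shared fixtures: designs, generator configs, and cached fits.

Expensive simulation batches (null-model fits, bootstrap coverage runs) are
session-scoped so property tests and acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import tpcurve as tp
from tpcurve.data_model import ExperimentDesign

ASSAY_TEMPS = (10.0, 13.0, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0, 27.0, 28.0)


def reduced_design(n_blocks: int = 5, n_per_vial: int = 15) -> ExperimentDesign:
    """Smaller layout used for simulation-heavy tests: 2 replicates per
    combination (1 at 27 degC) so the per-block temperature cap is feasible
    with few blocks."""
    reps = {t: (1 if t == 27.0 else 2) for t in ASSAY_TEMPS}
    return ExperimentDesign(
        n_per_vial=n_per_vial, replicates_per_combo=reps, n_blocks=n_blocks
    )


@pytest.fixture(scope="session")
def paper_design():
    return tp.default_design()


@pytest.fixture(scope="session")
def small_design():
    return reduced_design()


@pytest.fixture(scope="session")
def paper_table():
    """One full-design dataset with distinct group optima."""
    cfg = tp.paper_like_config({18.0: 19.0, 20.0: 20.0, 22.0: 21.2}, seed=101)
    return tp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def paper_fit(paper_table):
    fit = tp.fit_glmm(paper_table)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def small_table(small_design):
    cfg = tp.paper_like_config(
        {18.0: 19.0, 20.0: 20.0, 22.0: 21.2}, seed=202, design=small_design
    )
    return tp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_table):
    fit = tp.fit_glmm(small_table)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def small_boot(small_fit):
    """A moderate bootstrap on the reduced design, reused across tests."""
    return tp.parametric_bootstrap(small_fit, B=80, seed=909)


def make_fit_from_poly(coeffs, design=None, spec=None):
    """GLMMFit whose every treatment cell encodes the given logit-scale
    polynomial (ascending raw coefficients), with identity vcov.

    Used to test descriptor extraction and curve prediction against known
    curves without running the optimizer.
    """
    from tpcurve.glmm_fit import GLMMFit, ModelSpec, _model_matrix
    from tpcurve.poly_basis import build_basis, evaluate_basis
    import pandas as pd

    design = design or tp.default_design()
    spec = spec or ModelSpec()
    temps = np.array(design.assay_temps)
    basis = build_basis(temps, degree=spec.degree)
    # express the target polynomial in [1, basis columns]
    nodes = np.linspace(temps.min(), temps.max(), spec.degree + 1)
    target = np.polynomial.polynomial.polyval(nodes, np.asarray(coeffs, dtype=float))
    Bm = np.column_stack([np.ones_like(nodes), evaluate_basis(basis, nodes)])
    w = np.linalg.solve(Bm, target)

    agg = pd.DataFrame({
        "fert_temp": np.repeat(design.fert_temps, len(design.embryo_temps)),
        "embryo_temp": np.tile(design.embryo_temps, len(design.fert_temps)),
        "assay_temp": temps[0],
    })
    X, names, term_cols, col_map = _model_matrix(
        agg, basis, spec, tuple(design.fert_temps), tuple(design.embryo_temps)
    )
    beta = np.zeros(X.shape[1])
    for d in range(spec.degree + 1):
        beta[col_map[(0, d)]] = w[d]   # factor-cell column 0 is the constant
    return GLMMFit(
        beta=beta, beta_names=names, vcov_beta=np.eye(len(beta)),
        sigma_block=0.0, sigma_vial=0.0, loglik=0.0, converged=True,
        message="synthetic", basis=basis, spec=spec,
        fert_levels=tuple(design.fert_temps),
        embryo_levels=tuple(design.embryo_temps),
        term_cols=term_cols, col_map=col_map,
    )
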