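import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit

import tpcurve as tp
from tpcurve.data_model import SurvivalTable
from tpcurve.glmm_fit import ModelSpec, _irls_glm, _prepare_state

from conftest import reduced_design


def test_modelspec_fixed_count():
    spec = ModelSpec(degree=3)
    assert spec.n_fixed(2, 3) == 24


def test_modelspec_validation():
    with pytest.raises(ValueError):
        ModelSpec(coding="helmert")
    with pytest.raises(ValueError):
        ModelSpec(degree=0)


# ---------------------------------------------------------------------------
# GLM core


def test_intercept_only_half_successes_closed_form():
    X = np.ones((1, 1))
    beta, _, _, ok = _irls_glm(X, np.array([15.0]), np.array([30.0]))
    assert ok
    assert beta[0] == pytest.approx(0.0, abs=1e-8)


def test_intercept_only_26_of_30_closed_form():
    X = np.ones((1, 1))
    beta, _, _, ok = _irls_glm(X, np.array([26.0]), np.array([30.0]))
    assert ok
    assert beta[0] == pytest.approx(np.log(26 / 4), abs=1e-8)
    assert beta[0] == pytest.approx(1.8718, abs=1e-4)


def test_fit_glm_matches_statsmodels_oracle(small_table):
    fit = tp.fit_glm(small_table)
    state, succ = _prepare_state(small_table, fit.spec)
    m = sm.GLM(
        np.column_stack([succ, state.trials - succ]), state.X,
        family=sm.families.Binomial(),
    ).fit()
    assert np.allclose(fit.beta, m.params, atol=1e-8)
    assert np.allclose(np.sqrt(np.diag(fit.vcov_beta)), m.bse, rtol=1e-6)


# ---------------------------------------------------------------------------
# GLMM


def test_zero_variance_data_reduces_to_glm():
    cfg = tp.paper_like_config(
        {18.0: 19.0, 20.0: 20.0, 22.0: 21.2}, seed=7,
        sigma_block=0.0, sigma_vial=0.0,
    )
    table = tp.simulate_dataset(cfg)
    assert len(table) == 6840
    fm = tp.fit_glmm(table)
    fg = tp.fit_glm(table)
    assert fm.converged
    assert fm.sigma_block <= 0.05 and fm.sigma_vial <= 0.05
    assert fm.boundary_flags["sigma_block"] and fm.boundary_flags["sigma_vial"]
    se = np.sqrt(np.diag(fg.vcov_beta))
    assert np.all(np.abs(fm.beta - fg.beta) < 3 * se)


def test_all_ones_flags_separation():
    cfg = tp.paper_like_config(
        {18.0: 19.0, 20.0: 20.0, 22.0: 21.2}, seed=7,
        peak_logit=40.0, quad=-0.001, sigma_block=0.0, sigma_vial=0.0,
    )
    table = tp.simulate_dataset(cfg)
    assert all(r.outcome == 1 for r in table.records)
    fit = tp.fit_glmm(table)
    assert not fit.converged
    assert "separation" in fit.message


def test_loglik_nesting(small_table):
    fm = tp.fit_glmm(small_table)
    fg = tp.fit_glm(small_table)
    assert fm.loglik >= fg.loglik - 1e-4


def test_row_permutation_invariance(small_table):
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(small_table.records))
    shuffled = SurvivalTable(
        records=[small_table.records[i] for i in perm], design=small_table.design
    )
    f1 = tp.fit_glmm(small_table)
    f2 = tp.fit_glmm(shuffled)
    assert np.all(np.abs(f1.beta - f2.beta) < 1e-6)
    assert abs(f1.sigma_block - f2.sigma_block) < 1e-6
    assert abs(f1.sigma_vial - f2.sigma_vial) < 1e-6


def test_vcov_symmetric_psd(small_fit):
    V = small_fit.vcov_beta
    assert np.allclose(V, V.T, atol=1e-12)
    assert np.linalg.eigvalsh(V).min() > -1e-10


def test_parameter_recovery_simulation(small_design):
    """Fitted betas stay within 4 SEs of the generating truth.

    The true logit curve is an exact cubic per treatment cell, so the true
    beta in the fitted parameterization is the exact solution of
    X beta = eta_true over the design rows (the model is cell-saturated).
    """
    hits = 0
    n_rep = 20
    for s in range(n_rep):
        cfg = tp.paper_like_config(
            {18.0: 19.0, 20.0: 20.0, 22.0: 21.2}, seed=1000 + s, design=small_design
        )
        fit = tp.fit_glmm(tp.simulate_dataset(cfg))
        if not fit.converged:
            continue
        state = fit._state
        agg = state.agg
        eta_true = np.array([
            float(cfg.curve_params[(row.fert_temp, row.embryo_temp)].eta(row.assay_temp))
            for row in agg.itertuples(index=False)
        ])
        beta_truth, res, rank, _ = np.linalg.lstsq(state.X, eta_true, rcond=None)
        assert rank == state.X.shape[1]
        se = np.sqrt(np.diag(fit.vcov_beta))
        if np.all(np.abs(fit.beta - beta_truth) < 4 * se):
            hits += 1
    assert hits >= int(0.85 * n_rep)


def test_sigma_block_recovery_is_monotone(small_design):
    """Fitted sigma_block increases with the generating SD (rank corr > 0)."""
    from scipy.stats import spearmanr

    sds = [0.05, 0.2, 0.4, 0.8, 1.2]
    fitted = []
    for i, sd in enumerate(sds):
        ests = []
        for s in range(6):
            cfg = tp.paper_like_config(
                {18.0: 19.0, 20.0: 20.0, 22.0: 21.2},
                seed=5000 + 100 * i + s, design=small_design,
                sigma_block=sd, sigma_vial=0.3,
            )
            fit = tp.fit_glmm(tp.simulate_dataset(cfg))
            ests.append(fit.sigma_block)
        fitted.append(np.mean(ests))
    rho, _ = spearmanr(sds, fitted)
    assert rho > 0


def test_rank_deficient_design_names_aliased_terms(small_table):
    # duplicate an embryo level into the fert factor? construct collinearity by
    # making all fert temps identical -> fert dummy column becomes all zero
    recs = [
        type(r)(r.block_id, r.vial_id, 18.0, r.embryo_temp, r.assay_temp, r.outcome)
        for r in small_table.records
    ]
    table = SurvivalTable(records=recs, design=small_table.design)
    # with a single fert level the model matrix drops the F columns entirely,
    # so instead force degree above the number of distinct temps minus 1
    with pytest.raises(ValueError):
        tp.fit_glmm(table, ModelSpec(degree=10))


def test_fit_serialization_roundtrip(small_fit, tmp_path):
    from tpcurve.cli import load_fit, save_fit

    p = tmp_path / "fit.json"
    save_fit(small_fit, p)
    back = load_fit(p)
    assert np.allclose(back.beta, small_fit.beta)
    assert np.allclose(back.vcov_beta, small_fit.vcov_beta)
    assert back.sigma_block == pytest.approx(small_fit.sigma_block)
    assert back.term_cols == small_fit.term_cols
    assert back.col_map == small_fit.col_map
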