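"""Logit and random-intercept logit fits, AIC and best-subset selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from urispec import (LogitModel, RandomInterceptLogitModel, best_subset)
from urispec.exceptions import (DegenerateOutcomeError, SchemaError,
                                SelectionFailureError)


def _sim_logit(rng, n, beta, sd_b=0.0, m_per_group=1):
    G = n // m_per_group
    g = np.repeat(np.arange(G), m_per_group)
    x = rng.normal(size=(n, len(beta) - 1))
    b = rng.normal(0, sd_b, G)[g] if sd_b > 0 else 0.0
    eta = beta[0] + x @ np.asarray(beta[1:]) + b
    y = (rng.random(n) < expit(eta)).astype(int)
    return y, x, g


# ---------------------------------------------------------------------------
# plain logistic regression

def test_intercept_only_closed_form(rng):
    y = np.array([1, 1, 0, 0, 0, 1, 0, 0])
    res = LogitModel(y, np.empty((8, 0))).fit()
    assert res.params[0] == pytest.approx(logit(y.mean()), abs=1e-8)


def test_loglik_matches_direct_bernoulli_sum(rng):
    y, x, _ = _sim_logit(rng, 10, [0.2, 1.0])
    res = LogitModel(y, x).fit()
    p = expit(np.column_stack([np.ones(10), x]) @ res.params)
    direct = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert res.llf == pytest.approx(direct, abs=1e-8)


def test_simulated_coefficients_recovered_within_3se(rng):
    beta = np.array([-0.5, 1.2, -0.8])
    y, x, _ = _sim_logit(rng, 5000, beta)
    res = LogitModel(y, x).fit()
    assert res.converged
    np.testing.assert_array_less(np.abs(res.params - beta), 3 * res.bse)


def test_loglik_is_local_maximum(rng):
    y, x, _ = _sim_logit(rng, 300, [0.1, 0.7])
    res = LogitModel(y, x).fit()

    def ll(beta):
        eta = np.column_stack([np.ones(300), x]) @ beta
        return float(np.sum(y * eta - np.logaddexp(0, eta)))

    for delta in ([0.01, 0], [0, -0.01], [0.005, 0.005]):
        assert ll(res.params) >= ll(res.params + delta)


def test_perfect_separation_flagged_not_silent():
    x = np.linspace(-2, 2, 40).reshape(-1, 1)
    y = (x[:, 0] > 0).astype(int)
    res = LogitModel(y, x).fit()
    assert res.separation_flag and not res.converged


def test_single_class_outcome_rejected():
    with pytest.raises(DegenerateOutcomeError):
        LogitModel(np.ones(10), np.random.default_rng(0).normal(size=(10, 1)))


def test_aic_identity_and_predict(rng):
    y, x, _ = _sim_logit(rng, 200, [0.0, 0.5])
    res = LogitModel(y, x).fit()
    assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_params, abs=1e-9)
    zero = res.params * 0.0
    res_zero = LogitModel(y, x).fit()
    res_zero.params = zero
    np.testing.assert_allclose(res_zero.predict(x), 0.5)


def test_predict_matches_hand_logistic():
    y = np.array([0, 1, 0, 1])
    x = np.array([[0.0], [1.0], [2.0], [3.0]])
    res = LogitModel(y, x).fit()
    res.params = np.array([0.5, -0.25])
    expected = 1.0 / (1.0 + np.exp(-(0.5 - 0.25 * x[:, 0])))
    np.testing.assert_allclose(res.predict(x), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# random-intercept logit

@pytest.fixture(scope="module")
def tiny_mixed_fixture():
    y = np.array([1, 0, 1, 1, 0, 1])
    x = np.array([[0.3], [-1.2], [0.5], [1.0], [-0.4], [0.1]])
    g = np.array([0, 0, 1, 1, 2, 2])
    return y, x, g


def dense_marginal_loglik(y, x, g, theta, grid_points=200_001):
    """Trapezoidal integration of the random-intercept likelihood."""
    beta, s = theta[:-1], theta[-1]
    eta = np.column_stack([np.ones(len(y)), x]) @ beta
    total = 0.0
    bgrid = np.linspace(-10 * s, 10 * s, grid_points)
    dens = np.exp(-0.5 * (bgrid / s) ** 2) / np.sqrt(2 * np.pi * s * s)
    for grp in np.unique(g):
        idx = g == grp
        p = expit(eta[idx][:, None] + bgrid[None, :])
        lik = np.prod(np.where(y[idx][:, None] == 1, p, 1 - p), axis=0)
        total += np.log(np.trapezoid(lik * dens, bgrid))
    return total


def test_marginal_loglik_matches_dense_integration(tiny_mixed_fixture):
    y, x, g = tiny_mixed_fixture
    model = RandomInterceptLogitModel(y, x, g, n_quadrature=15)
    theta = np.array([0.5, -0.3, 0.8])
    agq = model.loglik(theta)
    dense = dense_marginal_loglik(y, x, g, theta)
    assert agq == pytest.approx(dense, abs=1e-6)


def test_quadrature_converged_at_default_node_count(tiny_mixed_fixture):
    y, x, g = tiny_mixed_fixture
    theta = np.array([0.2, 0.9, 1.3])
    ll15 = RandomInterceptLogitModel(y, x, g, n_quadrature=15).loglik(theta)
    ll25 = RandomInterceptLogitModel(y, x, g, n_quadrature=25).loglik(theta)
    assert abs(ll15 - ll25) < 1e-6


def test_sigma_zero_collapses_to_plain_logit(rng):
    # data without any patient effect: sigma_b is estimated on the boundary
    # and the fixed effects collapse to the plain logit solution
    y, x, g = _sim_logit(rng, 400, [-0.3, 0.9], sd_b=0.0, m_per_group=4)
    lr = LogitModel(y, x).fit()
    mixed = RandomInterceptLogitModel(y, x, g)
    assert mixed.loglik(np.append(lr.params, 0.0)) == pytest.approx(lr.llf,
                                                                    abs=1e-10)
    res = mixed.fit()
    assert res.boundary_flag and res.sigma_b < 1e-4
    np.testing.assert_allclose(res.params, lr.params, atol=1e-4)


def test_lrre_aic_counts_variance_component(rng):
    y, x, g = _sim_logit(rng, 120, [0.0, 0.8], sd_b=1.0, m_per_group=4)
    res = RandomInterceptLogitModel(y, x, g).fit(compute_bse=False)
    assert res.n_params == 3  # intercept + slope + sigma_b
    assert res.aic == pytest.approx(-2 * res.llf + 2 * 3, abs=1e-9)
    assert res.sigma_b >= 0


def test_lrre_matches_lme4_glmer(tmp_path, rng):
    """Independent oracle: lme4::glmer with adaptive quadrature (nAGQ=15)."""
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript expected on PATH for the lme4 oracle")
    y, x, g = _sim_logit(rng, 240, [-0.4, 1.1], sd_b=1.0, m_per_group=4)
    df = pd.DataFrame({"y": y, "x": x[:, 0], "g": g})
    csv = tmp_path / "fix.csv"
    df.to_csv(csv, index=False)
    script = (
        f"d <- read.csv('{csv}');"
        "suppressMessages(library(lme4));"
        "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15);"
        "cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)))"
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    b0, b1, sigma, llf = map(float, out.stdout.split())
    res = RandomInterceptLogitModel(y, x, g, n_quadrature=15).fit(
        compute_bse=False)
    assert res.params[0] == pytest.approx(b0, abs=2e-3)
    assert res.params[1] == pytest.approx(b1, abs=2e-3)
    assert res.sigma_b == pytest.approx(sigma, abs=2e-3)
    assert res.llf == pytest.approx(llf, abs=1e-3)


def test_conditional_prediction_uses_blups(rng):
    y, x, g = _sim_logit(rng, 200, [0.0, 0.6], sd_b=1.2, m_per_group=4)
    res = RandomInterceptLogitModel(y, x, g).fit(compute_bse=False)
    cond = res.predict(x, groups=g, mode="conditional")
    marg = res.predict(x, groups=g, mode="marginal")
    b = np.array([res.random_effects[k] for k in g])
    eta = np.column_stack([np.ones(200), x]) @ res.params
    np.testing.assert_allclose(cond, expit(eta + b), atol=1e-12)
    np.testing.assert_allclose(marg, expit(eta), atol=1e-12)
    # unseen patients fall back to the population (marginal) prediction
    unseen = res.predict(x[:3], groups=["nope"] * 3, mode="conditional")
    np.testing.assert_allclose(unseen, marg[:3], atol=1e-12)


def test_prediction_schema_mismatch_raises(rng):
    y, x, g = _sim_logit(rng, 60, [0.0, 0.5])
    res = LogitModel(y, pd.DataFrame({"a": x[:, 0]})).fit()
    with pytest.raises(SchemaError):
        res.predict(pd.DataFrame({"b": x[:, 0]}))


# ---------------------------------------------------------------------------
# best-subset selection

def test_three_candidates_fit_seven_subsets_plus_baseline(rng):
    y, x, _ = _sim_logit(rng, 150, [0.0, 1.0, 0.0, 0.0])
    X = pd.DataFrame(x, columns=["a", "b", "c"])
    sel = best_subset(X, y, kind="lr")
    assert sel.n_fits == 8  # 2^3 - 1 subsets + intercept-only baseline
    assert ("a",) in [t.features for t in sel.trials]


def test_best_aic_equals_independent_enumeration(rng):
    import itertools
    y, x, _ = _sim_logit(rng, 200, [0.2, 0.9, -0.5, 0.0])
    X = pd.DataFrame(x, columns=["a", "b", "c"])
    sel = best_subset(X, y, kind="lr")
    aics = [LogitModel(y, np.empty((200, 0))).fit().aic]
    for size in (1, 2, 3):
        for feats in itertools.combinations(["a", "b", "c"], size):
            aics.append(LogitModel(y, X[list(feats)]).fit().aic)
    assert sel.best.aic == pytest.approx(min(aics), abs=1e-9)


def test_selection_invariant_to_column_order(rng):
    y, x, _ = _sim_logit(rng, 300, [0.0, 1.2, 0.6, 0.0])
    X = pd.DataFrame(x, columns=["a", "b", "c"])
    s1 = best_subset(X, y, kind="lr")
    s2 = best_subset(X[["c", "a", "b"]], y, kind="lr")
    assert sorted(s1.selected_features) == sorted(s2.selected_features)
    assert s1.best.aic == pytest.approx(s2.best.aic, abs=1e-9)


def test_lrre_subset_selection_runs(rng):
    y, x, g = _sim_logit(rng, 160, [0.0, 1.0, 0.0], sd_b=0.8, m_per_group=4)
    X = pd.DataFrame(x, columns=["a", "b"])
    sel = best_subset(X, y, groups=g, kind="lrre")
    assert sel.n_fits == 4
    assert sel.best.kind == "LRRE"


def test_no_convergent_subset_raises():
    x = np.linspace(-2, 2, 40).reshape(-1, 1)
    y = (x[:, 0] > 0).astype(int)  # the only candidate separates perfectly
    with pytest.raises(SelectionFailureError):
        best_subset(pd.DataFrame({"sep": x[:, 0]}), y, kind="lr",
                    include_baseline=False)


def test_candidate_cap_enforced(rng):
    y, x, _ = _sim_logit(rng, 60, [0.0] + [0.1] * 13)
    X = pd.DataFrame(x, columns=[f"c{i}" for i in range(13)])
    with pytest.raises(ValueError, match="hard cap"):
        best_subset(X, y, kind="lr")
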