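"""Cox engine: optimality, reference agreement, Wald/LRT behaviour."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats
from sksurv.linear_model import CoxPHSurvivalAnalysis

from survinteract import PartialLikelihood, fit_cox, lrt_p, wald_p, wald_stat
from conftest import brute_force_partial_loglik


def _random_survival(seed, n=60, p=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.normal(size=n), rng.uniform(size=n)])[:, :p]
    beta = np.array([0.5, -0.3])[:p]
    t = rng.exponential(1.0 / np.exp(X @ beta))
    c = rng.exponential(2.0, size=n)
    return np.minimum(t, c), (t <= c).astype(int), X


def test_beta_matches_grid_oracle_on_tiny_dataset():
    """Newton optimum equals a brute-force grid maximization on 6 subjects."""
    time = np.array([2.0, 3.5, 1.1, 4.2, 0.7, 5.0])
    event = np.array([1, 0, 1, 1, 1, 0])
    X = np.array([[0.2], [1.4], [-0.5], [0.8], [-1.1], [0.3]])
    grid = np.arange(-5.0, 5.0, 1e-4)
    lls = [brute_force_partial_loglik(time, event, X, [b]) for b in grid]
    b_star = grid[int(np.argmax(lls))]
    fit = fit_cox(time, event, X)
    assert fit.converged
    assert abs(fit.beta[0] - b_star) < 1e-4


def test_score_vanishes_at_optimum():
    time, event, X = _random_survival(1, n=120)
    fit = fit_cox(time, event, X)
    assert fit.converged
    assert fit.score_norm < 1e-6


def test_loglik_at_least_null():
    for seed in range(5):
        time, event, X = _random_survival(seed)
        fit = fit_cox(time, event, X)
        assert fit.loglik >= fit.loglik_null - 1e-10


@pytest.mark.parametrize("seed", range(50))
def test_agrees_with_reference_implementation(seed):
    """Coefficients match an independently fitted Cox model to 1e-6 and the
    covariance matches the inverse finite-difference Hessian of an
    independent partial-likelihood oracle to 1e-5 relative."""
    time, event, X = _random_survival(seed, n=60)
    fit = fit_cox(time, event, X)
    assert fit.converged
    y = np.array(
        [(bool(e), t) for e, t in zip(event, time)], dtype=[("e", bool), ("t", float)]
    )
    ref = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200).fit(X, y)
    np.testing.assert_allclose(fit.beta, ref.coef_, atol=1e-6)
    # numerical Hessian of the oracle log partial likelihood at the optimum
    h = 1e-4
    p = X.shape[1]
    H = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            pts = []
            for si in (1, -1):
                for sj in (1, -1):
                    b = fit.beta.copy()
                    b[i] += si * h
                    b[j] += sj * h
                    pts.append(si * sj * brute_force_partial_loglik(time, event, X, b))
            H[i, j] = sum(pts) / (4 * h * h)
    cov_oracle = np.linalg.inv(-H)
    np.testing.assert_allclose(fit.covariance, cov_oracle, rtol=1e-5)


def test_loglik_agrees_with_lifelines():
    time, event, X = _random_survival(7, n=100)
    fit = fit_cox(time, event, X)
    df = pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "T": time, "E": event})
    cph = CoxPHFitter().fit(df, "T", "E")
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_arm_symmetric_dataset_gives_zero_coefficient():
    """Pairs identical except for the arm label: swapping labels maps the data
    to itself, so the treatment coefficient must be zero."""
    z_times = [(1.0, 1), (2.5, 1), (4.0, 0), (0.7, 1)]
    time = np.array([t for t, _ in z_times for _ in (0, 1)])
    event = np.array([e for _, e in z_times for _ in (0, 1)])
    arm = np.array([0, 1] * len(z_times), dtype=float)
    fit = fit_cox(time, event, arm[:, None])
    assert fit.converged
    assert abs(fit.beta[0]) < 1e-8


def test_weighted_fit_scale_invariance():
    time, event, X = _random_survival(11)
    base = fit_cox(time, event, X)
    scaled = fit_cox(time, event, X, weights=np.full(len(time), 3.7))
    np.testing.assert_allclose(scaled.beta, base.beta, atol=1e-8)


def test_weighted_fit_matches_weighted_oracle():
    rng = np.random.default_rng(5)
    time, event, X = _random_survival(5, n=40, p=1)
    w = rng.uniform(0.2, 1.5, size=40)
    fit = fit_cox(time, event, X, weights=w)
    grid = np.arange(-5.0, 5.0, 1e-4)
    lls = [brute_force_partial_loglik(time, event, X, [b], weights=w) for b in grid]
    assert abs(fit.beta[0] - grid[int(np.argmax(lls))]) < 1e-4


def test_separation_is_flagged_not_raised():
    # covariate perfectly ordered with event times: monotone likelihood
    time = np.arange(1.0, 9.0)
    event = np.ones(8, dtype=int)
    X = np.arange(8.0)[:, None]
    fit = fit_cox(time, event, X)
    assert not fit.converged


def test_no_events_rejected():
    with pytest.raises(ValueError, match="event"):
        PartialLikelihood(np.array([1.0, 2.0]), np.array([0, 0]))


def test_wald_p_values():
    time, event, X = _random_survival(2)
    fit = fit_cox(time, event, X)
    # synthetic fits with controlled beta/se exercise the formula directly
    from survinteract.cox import CoxFit

    def mk(b, v):
        return CoxFit(
            beta=np.array([b]), covariance=np.array([[v]]), loglik=0.0,
            loglik_null=0.0, converged=True, n_events=10, n_iter=1, score_norm=0.0,
        )

    assert wald_p(mk(0.0, 1.0), 0) == pytest.approx(1.0)
    assert wald_p(mk(1.959964, 1.0), 0) == pytest.approx(0.05, abs=1e-6)
    ps = [wald_p(mk(b, 1.0), 0) for b in (0.5, 1.0, 2.0, 3.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))  # strictly decreasing in |z|
    with pytest.raises(ValueError):
        wald_p(mk(1.0, 0.0), 0)
    assert wald_stat(mk(2.0, 4.0), 0) == pytest.approx(1.0)
    assert wald_p(fit, 0) == pytest.approx(
        2 * stats.norm.sf(abs(fit.beta[0]) / fit.se[0])
    )


def test_lrt_p_values():
    assert lrt_p(-100.0, -100.0, 3) == pytest.approx(1.0)
    assert lrt_p(-100.0 + 7.8147 / 2, -100.0, 3) == pytest.approx(0.05, abs=1e-4)
    assert lrt_p(-50.0 + 3.8415 / 2, -50.0, 1) == pytest.approx(0.05, abs=1e-4)
    assert lrt_p(-100.5, -100.0, 2) == pytest.approx(1.0)  # negative stat clamps
    with pytest.raises(ValueError):
        lrt_p(-1.0, -2.0, 0)
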