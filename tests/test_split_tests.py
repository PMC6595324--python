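"""Categorization-based tests: construction, invariances, oracle agreement."""

import numpy as np
import pytest

from survinteract import (
    TrialDataset,
    cox_linear_interaction_test,
    fit_cox,
    median_split_test,
    optimal_split_test,
    quartile_split_test,
    wald_p,
    wald_stat,
)
from survinteract.split_tests import _admissible_cutpoints
from conftest import make_trial


def _replace_z(data, z):
    return TrialDataset(z=z, arm=data.arm, time=data.time, event=data.event)


@pytest.mark.parametrize("n", [40, 41])
def test_median_split_group_sizes(n):
    data = make_trial(1, n, 0.3, seed=n)
    res = median_split_test(data)
    upper = int((data.z >= res.extras["cutpoint"]).sum())
    assert upper == int(np.ceil(n / 2))


def test_median_split_monotone_transform_invariance():
    data = make_trial(3, 150, 0.3, seed=8)
    res = median_split_test(data)
    res_t = median_split_test(_replace_z(data, data.z**3))
    assert res_t.p_value == pytest.approx(res.p_value, abs=1e-12)
    assert res_t.statistic == pytest.approx(res.statistic, abs=1e-9)


def test_median_split_matches_independent_refit():
    """Same three-term model refitted from scratch reproduces p to 1e-4."""
    data = make_trial(3, 500, 0.3, seed=17)
    res = median_split_test(data)
    group = (data.z >= np.median(data.z)).astype(float)
    X = np.column_stack([group, data.arm, group * data.arm])
    refit = fit_cox(data.time, data.event, X)
    assert res.p_value == pytest.approx(wald_p(refit, 2), abs=1e-4)


def test_quartile_split_df_and_groups():
    data = make_trial(6, 400, 0.3, seed=4)
    res = quartile_split_test(data)
    assert res.df == 3
    qs = np.asarray(res.extras["quartiles"])
    grp = np.searchsorted(qs, data.z, side="right")
    sizes = np.bincount(grp, minlength=4)
    assert sizes.max() - sizes.min() <= 1  # n divisible by 4


def test_quartile_split_lrt_is_loglik_difference():
    data = make_trial(5, 300, 0.3, seed=9)
    res = quartile_split_test(data)
    qs = np.quantile(data.z, [0.25, 0.5, 0.75])
    grp = np.searchsorted(qs, data.z, side="right")
    dummies = np.column_stack([(grp == g).astype(float) for g in (1, 2, 3)])
    arm = data.arm.astype(float)
    full = fit_cox(
        data.time, data.event,
        np.column_stack([dummies, arm, dummies * arm[:, None]]),
    )
    null = fit_cox(data.time, data.event, np.column_stack([dummies, arm]))
    assert res.statistic == pytest.approx(2 * (full.loglik - null.loglik), abs=1e-6)


def test_optimal_split_cutpoint_within_percentile_band():
    for seed in range(5):
        data = make_trial(2, 120, 0.3, seed=seed)
        res = optimal_split_test(data)
        zs = np.sort(data.z)
        k_min = int(np.ceil(0.1 * data.n))
        # midpoint cutpoints live between the k_min-th smallest and largest values
        assert zs[k_min - 1] <= res.extras["cutpoint"] <= zs[data.n - k_min]


def test_optimal_split_matches_bruteforce_scan():
    """Exhaustive per-cutpoint refits reproduce both the argmax and the max."""
    data = make_trial(3, 40, 0.3, seed=23)
    res = optimal_split_test(data)
    best_stat, best_cut = -np.inf, None
    for c in _admissible_cutpoints(data.z):
        group = (data.z >= c).astype(float)
        X = np.column_stack([group, data.arm, group * data.arm])
        fit = fit_cox(data.time, data.event, X)
        if not fit.converged:
            continue
        stat = wald_stat(fit, 2)
        if stat > best_stat:
            best_stat, best_cut = stat, c
    assert res.extras["cutpoint"] == pytest.approx(best_cut)
    assert res.statistic == pytest.approx(best_stat, rel=1e-8)


def test_optimal_split_dominates_median_split():
    for seed in range(5):
        data = make_trial(1, 100, 0.3, seed=100 + seed)
        med = median_split_test(data)
        opt = optimal_split_test(data)
        # the median cutpoint is always admissible (both halves hold 50%)
        assert opt.statistic >= med.statistic - 1e-9


def test_admissible_cutpoints_respect_minimum_fraction():
    z = np.random.default_rng(0).uniform(size=50)
    cuts = _admissible_cutpoints(z, min_frac=0.1)
    for c in cuts:
        assert 5 <= (z < c).sum() <= 45
    assert cuts.size == 41  # lower-group sizes 5..45 inclusive


def test_cox_linear_interaction_null_symmetric_dataset():
    """Arm-symmetric data: interaction and treatment coefficients vanish."""
    z = np.array([0.2, 0.4, 0.6, 0.8])
    time = np.array([2.0, 1.0, 4.0, 3.0])  # not monotone in z (no separation)
    event = np.array([1, 1, 1, 0])
    data = TrialDataset(
        z=np.repeat(z, 2),
        arm=np.tile([0, 1], 4),
        time=np.repeat(time, 2),
        event=np.repeat(event, 2),
    )
    res = cox_linear_interaction_test(data)
    assert abs(res.extras["beta_interaction"]) < 1e-7
    assert res.p_value == pytest.approx(1.0, abs=1e-5)


def test_failed_fit_reports_p_one():
    # two events total, none in the upper half: subgroup model cannot converge
    data = TrialDataset(
        z=np.linspace(0.01, 0.99, 24),
        arm=np.tile([0, 1], 12),
        time=np.concatenate([np.arange(1.0, 13.0), np.arange(20.0, 32.0)]),
        event=np.array([1] * 12 + [0] * 12),
    )
    res = quartile_split_test(data)
    if res.failed:
        assert res.p_value == 1.0
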