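"""Categorization-based interaction tests and the linear Cox interaction test.

Four procedures, each returning a :class:`~survinteract.results.TestResult`:

* ``median_split_test`` — dichotomize at the sample median, Wald test of the
  subgroup-by-treatment product term.
* ``quartile_split_test`` — four quartile subgroups (dummy coded, lowest as
  reference), 3-df likelihood-ratio test of the interaction block.
* ``optimal_split_test`` — scan all cutpoints whose two subgroups each hold
  at least 10% of the sample, pick the one maximizing the interaction Wald
  statistic, then test at that cutpoint as if it had been prespecified.
  This naive two-step procedure is known to be grossly anti-conservative
  (type-I error near 50%); it is implemented without any selection
  correction precisely so that behaviour can be studied.
* ``cox_linear_interaction_test`` — continuous biomarker, Wald test of the
  Z x T product term.

Conventions: subgroup membership is I(z >= cutpoint); boundary ties go to
the upper group; quartiles are type-7 empirical quantiles.
"""

from __future__ import annotations

import numpy as np

from .cox import PartialLikelihood, lrt_p, wald_p, wald_stat
from .datasets import TrialDataset
from .results import TestResult

__all__ = [
    "median_split_test",
    "quartile_split_test",
    "optimal_split_test",
    "cox_linear_interaction_test",
]


def _failed_result(method: str, df=None, **extras) -> TestResult:
    extras = {"failed": True, **extras}
    return TestResult(method=method, statistic=np.nan, p_value=1.0, df=df, extras=extras)


def _interaction_design(group: np.ndarray, arm: np.ndarray) -> np.ndarray:
    return np.column_stack([group, arm, group * arm])


def median_split_test(data: TrialDataset) -> TestResult:
    """Wald interaction test after splitting the biomarker at its median."""
    med = float(np.median(data.z))
    group = (data.z >= med).astype(float)
    pl = PartialLikelihood(data.time, data.event)
    fit = pl.fit(_interaction_design(group, data.arm))
    if not fit.converged:
        return _failed_result("median_split", df=1, cutpoint=med)
    return TestResult(
        method="median_split",
        statistic=wald_stat(fit, 2),
        p_value=wald_p(fit, 2),
        df=1,
        extras={"cutpoint": med, "beta_interaction": float(fit.beta[2])},
    )


def quartile_split_test(data: TrialDataset) -> TestResult:
    """3-df LRT for heterogeneity of the treatment effect across quartile groups."""
    qs = np.quantile(data.z, [0.25, 0.5, 0.75])  # type-7 interpolation
    grp = np.searchsorted(qs, data.z, side="right")  # ties go upward
    dummies = np.column_stack([(grp == g).astype(float) for g in (1, 2, 3)])
    arm = data.arm.astype(float)
    X_null = np.column_stack([dummies, arm])
    X_full = np.column_stack([dummies, arm, dummies * arm[:, None]])
    pl = PartialLikelihood(data.time, data.event)
    fit_null = pl.fit(X_null)
    fit_full = pl.fit(X_full)
    if not (fit_null.converged and fit_full.converged):
        return _failed_result("quartile_split", df=3)
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    return TestResult(
        method="quartile_split",
        statistic=stat,
        p_value=lrt_p(fit_full.loglik, fit_null.loglik, df=3),
        df=3,
        extras={"quartiles": tuple(float(q) for q in qs)},
    )


def _admissible_cutpoints(z: np.ndarray, min_frac: float = 0.1) -> np.ndarray:
    """Midpoints between consecutive order statistics leaving >= min_frac*n
    subjects on each side; degenerate midpoints (tied values) are dropped."""
    n = z.shape[0]
    zs = np.sort(z)
    k_min = int(np.ceil(min_frac * n))  # lower-group size at cut k is k
    ks = np.arange(k_min, n - k_min + 1)
    cuts = 0.5 * (zs[ks - 1] + zs[ks])
    valid = zs[ks] > zs[ks - 1]
    return np.unique(cuts[valid])


def optimal_split_test(data: TrialDataset, min_frac: float = 0.1) -> TestResult:
    """Maximally selected interaction Wald statistic, then a naive re-test.

    The cutpoint maximizing the interaction Wald statistic (subgroups each
    >= ``min_frac`` of the sample) defines the subgroups; the reported
    p-value treats them as prespecified, i.e. it is the uncorrected Wald
    p-value at the selected cutpoint.
    """
    cuts = _admissible_cutpoints(data.z, min_frac)
    if cuts.size == 0:
        raise ValueError("no admissible cutpoint (too many ties or n too small)")
    pl = PartialLikelihood(data.time, data.event)
    arm = data.arm.astype(float)
    best_stat = -np.inf
    best_cut = None
    best_fit = None
    beta0 = None
    for c in cuts:
        group = (data.z >= c).astype(float)
        fit = pl.fit(_interaction_design(group, arm), beta0=beta0)
        if not fit.converged:
            beta0 = None
            continue
        beta0 = fit.beta  # warm start: neighbouring cutpoints fit similarly
        stat = wald_stat(fit, 2)
        if stat > best_stat:
            best_stat, best_cut, best_fit = stat, float(c), fit
    if best_fit is None:
        return _failed_result("optimal_split", df=1)
    return TestResult(
        method="optimal_split",
        statistic=best_stat,
        p_value=wald_p(best_fit, 2),
        df=1,
        extras={
            "cutpoint": best_cut,
            "n_cutpoints": int(cuts.size),
            "beta_interaction": float(best_fit.beta[2]),
        },
    )


def cox_linear_interaction_test(data: TrialDataset) -> TestResult:
    """Wald test of the Z x T term in a Cox model with continuous Z."""
    arm = data.arm.astype(float)
    X = np.column_stack([data.z, arm, data.z * arm])
    fit = PartialLikelihood(data.time, data.event).fit(X)
    if not fit.converged:
        return _failed_result("cox_linear", df=1)
    return TestResult(
        method="cox_linear",
        statistic=wald_stat(fit, 2),
        p_value=wald_p(fit, 2),
        df=1,
        extras={"beta_interaction": float(fit.beta[2])},
    )
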