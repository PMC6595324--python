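"""Cox proportional-hazards fitting by Newton-Raphson on the partial likelihood.

Self-contained engine used by every interaction test in this package: Breslow
handling of ties, optional per-observation case weights (used by the locally
weighted estimates of :mod:`survinteract.lplb`), Wald and likelihood-ratio
tests.  Simulated times are continuous, so ties have probability zero; the
Breslow convention only matters for imported data.

The log partial likelihood with weights :math:`w_i` is

.. math::

    \\ell(\\beta) = \\sum_{i: d_i = 1} w_i \\Big( x_i^\\top \\beta
        - \\log \\sum_{j: t_j \\ge t_i} w_j e^{x_j^\\top \\beta} \\Big),

maximized by damped Newton-Raphson (step-halving when a step does not
improve the likelihood).  The covariance estimate is the inverse observed
information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "PartialLikelihood", "fit_cox", "wald_p", "wald_stat", "lrt_p"]

_MAX_ETA_SPREAD = 35.0  # relative-risk spread e^35: monotone likelihood (separation)


@dataclass(frozen=True)
class CoxFit:
    """Result of one Cox model fit.

    ``beta`` is on the log-hazard-ratio scale; ``covariance`` is the inverse
    observed information; ``loglik_null`` is the log partial likelihood at
    ``beta = 0``.  When ``converged`` is False the coefficients are not
    trustworthy and callers treat the associated test as a non-rejection.
    """

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_events: int
    n_iter: int
    score_norm: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


class PartialLikelihood:
    """Fitting context bound to one (time, event, weights) triple.

    Presorts the risk-set structure once so that many design matrices can be
    fitted cheaply against the same survival data (cutpoint scans, fractional
    polynomial searches).
    """

    def __init__(self, time, event, weights=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        n = time.shape[0]
        if weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape[0] != n:
                raise ValueError("weights length mismatch")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
        order = np.argsort(time, kind="stable")
        self._order = order
        self._t = time[order]
        self._d = event[order].astype(bool)
        self._w = w[order]
        # first index of each tie group: risk set of t_i = rows first[i]..n-1
        self._first = np.searchsorted(self._t, self._t, side="left")
        self.n = n
        self.n_events = int(self._d.sum())
        if self.n_events < 1:
            raise ValueError("at least one observed event is required")
        self._wd = self._w[self._d]
        self._loglik_null = None

    @property
    def loglik_null(self) -> float:
        """Log partial likelihood at beta = 0 (design-independent)."""
        if self._loglik_null is None:
            s0 = np.cumsum(self._w[::-1])[::-1][self._first]
            self._loglik_null = float(-(self._wd * np.log(s0[self._d])).sum())
        return self._loglik_null

    def _ll_grad_info(self, Xs, beta, need_derivs=True):
        # overflow in a trial step (diverging beta) is handled by reporting
        # -inf, which makes the step-halving loop back off
        with np.errstate(over="ignore", invalid="ignore"):
            eta = Xs @ beta
            r = self._w * np.exp(eta)
            if not np.all(np.isfinite(r)):
                return -np.inf, None, None
            s0 = np.cumsum(r[::-1])[::-1][self._first]
            d = self._d
            ll = float((self._wd * (eta[d] - np.log(s0[d]))).sum())
            if not need_derivs:
                return ll, None, None
            rx = r[:, None] * Xs
            s1 = np.cumsum(rx[::-1], axis=0)[::-1][self._first]
            xbar = s1[d] / s0[d, None]
            grad = (self._wd[:, None] * (Xs[d] - xbar)).sum(axis=0)
            rxx = rx[:, :, None] * Xs[:, None, :]
            s2 = np.cumsum(rxx[::-1], axis=0)[::-1][self._first]
            info = (
                self._wd[:, None, None]
                * (s2[d] / s0[d, None, None] - xbar[:, :, None] * xbar[:, None, :])
            ).sum(axis=0)
        if not (np.isfinite(ll) and np.all(np.isfinite(grad)) and np.all(np.isfinite(info))):
            return -np.inf, None, None
        return ll, grad, info

    def fit(self, X, beta0=None, max_iter=50, tol=1e-8) -> CoxFit:
        """Maximize the weighted log partial likelihood for design ``X``.

        ``X`` is in original observation order, shape (n, p).  Returns a
        :class:`CoxFit`; non-convergence (including separation, detected by
        a diverging coefficient) is flagged rather than raised.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n:
            raise ValueError("design matrix row count mismatch")
        p = X.shape[1]
        Xs = X[self._order]
        beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        ll, grad, info = self._ll_grad_info(Xs, beta)
        if grad is None:  # unusable warm start
            beta = np.zeros(p)
            ll, grad, info = self._ll_grad_info(Xs, beta)
        converged = False
        diverged = False
        it = 0
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                break
            new_beta = beta + step
            new_ll, new_grad, new_info = self._ll_grad_info(Xs, new_beta)
            n_half = 0
            while new_ll < ll and n_half < 25:
                step *= 0.5
                new_beta = beta + step
                new_ll, new_grad, new_info = self._ll_grad_info(Xs, new_beta)
                n_half += 1
            if new_ll < ll:  # no uphill step found
                break
            delta = new_ll - ll
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            eta = Xs @ beta
            if eta.max() - eta.min() > _MAX_ETA_SPREAD:
                diverged = True
                break
            if delta <= tol * (1.0 + abs(ll)):
                if converged:  # second consecutive small change: polished
                    break
                converged = True  # take one more polishing step
            else:
                converged = False
        score_norm = float(np.linalg.norm(grad)) if grad is not None else np.inf
        cov = np.full((p, p), np.nan)
        if info is not None:
            try:
                cov = np.linalg.inv(info)
                cov = 0.5 * (cov + cov.T)
                if np.any(np.diag(cov) <= 0):
                    converged = False
            except np.linalg.LinAlgError:
                converged = False
        if diverged:
            converged = False
        return CoxFit(
            beta=beta,
            covariance=cov,
            loglik=ll,
            loglik_null=self.loglik_null,
            converged=converged,
            n_events=self.n_events,
            n_iter=it,
            score_norm=score_norm,
        )


def fit_cox(time, event, X, weights=None, beta0=None, max_iter=50, tol=1e-8) -> CoxFit:
    """Fit a (weighted) Cox model; convenience wrapper over :class:`PartialLikelihood`."""
    return PartialLikelihood(time, event, weights).fit(
        X, beta0=beta0, max_iter=max_iter, tol=tol
    )


def wald_stat(fit: CoxFit, term_index: int) -> float:
    """Squared Wald z (chi-square, 1 df) for one coefficient."""
    se = fit.se[term_index]
    if not se > 0:
        raise ValueError("standard error is zero; Wald statistic undefined")
    return float((fit.beta[term_index] / se) ** 2)


def wald_p(fit: CoxFit, term_index: int) -> float:
    """Two-sided Wald p-value for one coefficient, normal reference."""
    se = fit.se[term_index]
    if not se > 0:
        raise ValueError("standard error is zero; Wald test undefined")
    z = abs(fit.beta[term_index]) / se
    return float(2.0 * stats.norm.sf(z))


def lrt_p(loglik_full: float, loglik_null: float, df: int) -> float:
    """Likelihood-ratio p-value; negative statistics are clamped to zero."""
    if df <= 0:
        raise ValueError("df must be positive")
    stat = max(0.0, 2.0 * (loglik_full - loglik_null))
    return float(stats.chi2.sf(stat, df))
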