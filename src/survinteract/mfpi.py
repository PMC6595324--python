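"""Fractional-polynomial interaction tests (MFPI), FP2-flex1 and FP1-flex3.

Fractional polynomials transform the biomarker with powers from
``{-2, -1, -0.5, 0, 0.5, 1, 2, 3}`` (power 0 meaning log; a repeated FP2
power ``(p, p)`` meaning ``(z^p, z^p log z)``), giving 8 FP1 candidates and
36 FP2 candidates (28 distinct pairs + 8 repeated).

Two strategies for the interaction test:

* **FP2-flex1** — choose the FP2 pair maximizing the log partial likelihood
  of the *main-effects* model Cox(T, f1(z), f2(z)); keep those powers and
  compare against the model adding the two interaction terms with a 2-df
  likelihood-ratio test.  Selection is blind to the interaction, so the test
  is well calibrated.
* **FP1-flex3** — choose the best FP1 power separately in the model without
  and with the interaction term and compare the two selected models by a
  1-df likelihood-ratio test.  The two models may be non-nested and the
  double selection is not corrected for, which inflates the type-I error to
  roughly 10%; the inflation is a documented property of the strategy, not
  a defect of this implementation.

The biomarker must be strictly positive (the simulator guarantees z > 0).
Selection is deterministic: likelihood ties break toward the smaller
power(s) via the fixed candidate ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import PartialLikelihood, lrt_p
from .datasets import TrialDataset
from .results import TestResult

__all__ = [
    "FP_POWERS",
    "FpPowers",
    "fp_basis",
    "fp2_candidates",
    "mfpi_fp2_flex1_test",
    "mfpi_fp1_flex3_test",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FpPowers:
    """A degree-1 or degree-2 fractional-polynomial transformation."""

    powers: tuple[float, ...]

    def __post_init__(self):
        if len(self.powers) not in (1, 2):
            raise ValueError("FP degree must be 1 or 2")
        if any(p not in FP_POWERS for p in self.powers):
            raise ValueError(f"powers must come from {FP_POWERS}")
        if len(self.powers) == 2 and self.powers[0] > self.powers[1]:
            raise ValueError("FP2 powers must be ordered p1 <= p2")

    @property
    def degree(self) -> int:
        return len(self.powers)


def _xp(z: np.ndarray, p: float) -> np.ndarray:
    return np.log(z) if p == 0.0 else z**p


def fp_basis(z, powers: FpPowers) -> np.ndarray:
    """Transformed column(s) for a fractional polynomial, shape (n, degree).

    Power 0 is the logarithm; a repeated FP2 power (p, p) yields
    ``(z^p, z^p log z)``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("fractional polynomials require strictly positive z")
    if powers.degree == 1:
        return _xp(z, powers.powers[0])[:, None]
    p1, p2 = powers.powers
    col1 = _xp(z, p1)
    col2 = col1 * np.log(z) if p1 == p2 else _xp(z, p2)
    return np.column_stack([col1, col2])


def fp2_candidates() -> list[FpPowers]:
    """All 36 FP2 power pairs: 28 distinct combinations plus 8 repeated."""
    cands = []
    for i, p1 in enumerate(FP_POWERS):
        for p2 in FP_POWERS[i:]:
            cands.append(FpPowers((p1, p2)))
    return cands


def _best_fit(pl, arm, bases, with_interaction):
    """Deterministic argmax of the log partial likelihood over candidate bases."""
    best = None
    for powers, basis in bases:
        cols = [arm[:, None], basis]
        if with_interaction:
            cols.append(basis * arm[:, None])
        fit = pl.fit(np.hstack(cols))
        if not fit.converged:
            continue
        if best is None or fit.loglik > best[2].loglik:
            best = (powers, basis, fit)
    return best


def mfpi_fp2_flex1_test(data: TrialDataset) -> TestResult:
    """FP2-flex1: powers chosen on the main-effects model, 2-df interaction LRT."""
    pl = PartialLikelihood(data.time, data.event)
    arm = data.arm.astype(float)
    bases = [(pw, fp_basis(data.z, pw)) for pw in fp2_candidates()]
    best = _best_fit(pl, arm, bases, with_interaction=False)
    if best is None:
        return TestResult(
            method="mfpi_fp2_flex1", statistic=np.nan, p_value=1.0, df=2,
            extras={"failed": True},
        )
    powers, basis, fit_null = best
    fit_full = pl.fit(np.hstack([arm[:, None], basis, basis * arm[:, None]]))
    if not fit_full.converged:
        return TestResult(
            method="mfpi_fp2_flex1", statistic=np.nan, p_value=1.0, df=2,
            extras={"failed": True, "powers": powers.powers},
        )
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    return TestResult(
        method="mfpi_fp2_flex1",
        statistic=stat,
        p_value=lrt_p(fit_full.loglik, fit_null.loglik, df=2),
        df=2,
        extras={
            "powers": powers.powers,
            "beta_interaction": tuple(float(b) for b in fit_full.beta[3:5]),
        },
    )


def mfpi_fp1_flex3_test(data: TrialDataset) -> TestResult:
    """FP1-flex3: powers chosen separately with/without interaction, 1-df LRT.

    The compared models both contain the treatment term and one transformed
    biomarker column and differ by the single interaction coefficient, hence
    df = 1; when the selected powers differ the models are non-nested and the
    LRT is the (uncorrected) comparison the strategy prescribes.
    """
    pl = PartialLikelihood(data.time, data.event)
    arm = data.arm.astype(float)
    bases = [(FpPowers((p,)), fp_basis(data.z, FpPowers((p,)))) for p in FP_POWERS]
    best_null = _best_fit(pl, arm, bases, with_interaction=False)
    best_int = _best_fit(pl, arm, bases, with_interaction=True)
    if best_null is None or best_int is None:
        return TestResult(
            method="mfpi_fp1_flex3", statistic=np.nan, p_value=1.0, df=1,
            extras={"failed": True},
        )
    p_null, _, fit_null = best_null
    p_int, _, fit_int = best_int
    stat = 2.0 * (fit_int.loglik - fit_null.loglik)
    return TestResult(
        method="mfpi_fp1_flex3",
        statistic=stat,
        p_value=lrt_p(fit_int.loglik, fit_null.loglik, df=1),
        df=1,
        extras={
            "power_null": p_null.powers[0],
            "power_interaction": p_int.powers[0],
            "nested": p_null.powers == p_int.powers,
        },
    )


def treatment_effect_curve(data: TrialDataset, z_grid=None):
    """Plot hook: estimated log-HR(z) from the FP2-flex1 interaction model.

    Returns ``(z_grid, log_hr)`` on a grid of biomarker values (default 101
    points across the observed range).
    """
    res = mfpi_fp2_flex1_test(data)
    if res.failed:
        raise RuntimeError("FP2-flex1 model did not converge")
    powers = FpPowers(tuple(res.extras["powers"]))
    pl = PartialLikelihood(data.time, data.event)
    arm = data.arm.astype(float)
    basis = fp_basis(data.z, powers)
    fit = pl.fit(np.hstack([arm[:, None], basis, basis * arm[:, None]]))
    if z_grid is None:
        z_grid = np.linspace(data.z.min(), data.z.max(), 101)
    gb = fp_basis(z_grid, powers)
    log_hr = fit.beta[0] + gb @ fit.beta[3:5]
    return z_grid, log_hr
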