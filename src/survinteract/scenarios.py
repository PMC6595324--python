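"""Data-generating scenarios for a two-arm trial with a predictive biomarker.

Six scenarios define time-constant hazards ``lambda(z, arm)`` for event times
that are exponential given the biomarker ``Z ~ Uniform(0, 1)`` and the
randomized arm ``T ~ Bernoulli(1/2)``.  Scenarios 1-2 carry no
biomarker-treatment interaction (the hazard ratio between arms is constant
in ``z``); Scenarios 3-6 impose interactions of increasing complexity:

1. no effects at all: hazard 1 everywhere, HR(z) = 1
2. strong prognostic biomarker, constant HR(z) = 2
3. log-linear interaction, HR(z) = exp(0.75 z)
4. qualitative monotone interaction, HR crossing 1 at z = 0.424
5. late-onset interaction, HR(z) = (0.9 + 1.75 z^8)/0.9, reaching 2.94 at z=1
6. non-monotone (inverse-U) interaction, HR(z) = (5/3) exp(-0.9 (2z-1)^2)

Censoring is exponential and independent of everything else; rates 0.3 and 2
give roughly 25% and 67% censoring under Scenario 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .datasets import TrialDataset

__all__ = [
    "ScenarioSpec",
    "SimulationConfig",
    "get_scenario",
    "hazard",
    "true_hr",
    "simulate_trial",
    "SCENARIO_IDS",
]

SCENARIO_IDS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class ScenarioSpec:
    """Hazard functions of one simulation scenario.

    ``hazard_control`` / ``hazard_treated`` map a biomarker value in (0, 1)
    to an exponential event rate; ``true_hr`` is their ratio treated/control.
    """

    scenario_id: int
    hazard_control: Callable[[np.ndarray], np.ndarray]
    hazard_treated: Callable[[np.ndarray], np.ndarray]

    def true_hr(self, z):
        return self.hazard_treated(z) / self.hazard_control(z)


def _s1_control(z):
    return np.ones_like(np.asarray(z, dtype=float))


def _s2_control(z):
    return 0.5 * np.exp((2.0 * np.asarray(z) - 1.0) ** 2)


def _s2_treated(z):
    return np.exp((2.0 * np.asarray(z) - 1.0) ** 2)


def _s3_control(z):
    return 0.7 * np.exp(0.5 * np.asarray(z))


def _s3_treated(z):
    return 0.7 * np.exp(1.25 * np.asarray(z))


def _s4_control(z):
    return 0.9 * np.ones_like(np.asarray(z, dtype=float))


def _s4_treated(z):
    z = np.asarray(z, dtype=float)
    # exponent uses sqrt(z); the crossing HR(z)=1 sits at z=0.424
    return 0.35 * np.exp(1.7 * np.sqrt(z) - 0.2 * z**2 - 0.3 * z)


def _s5_treated(z):
    return 0.9 + 1.75 * np.asarray(z, dtype=float) ** 8


def _s6_control(z):
    return 0.75 * np.exp(0.4 * (2.0 * np.asarray(z) - 1.0) ** 2)


def _s6_treated(z):
    return 1.25 * np.exp(-0.5 * (2.0 * np.asarray(z) - 1.0) ** 2)


_SCENARIOS = {
    1: ScenarioSpec(1, _s1_control, _s1_control),
    2: ScenarioSpec(2, _s2_control, _s2_treated),
    3: ScenarioSpec(3, _s3_control, _s3_treated),
    4: ScenarioSpec(4, _s4_control, _s4_treated),
    5: ScenarioSpec(5, _s4_control, _s5_treated),
    6: ScenarioSpec(6, _s6_control, _s6_treated),
}


def get_scenario(scenario_id: int) -> ScenarioSpec:
    """Return the :class:`ScenarioSpec` for ``scenario_id`` in 1..6."""
    try:
        return _SCENARIOS[int(scenario_id)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"unknown scenario_id {scenario_id!r}; must be one of {SCENARIO_IDS}"
        ) from None


def hazard(spec: ScenarioSpec | int, z, arm: int):
    """Event hazard rate ``lambda(z, arm)``; constant in time."""
    if not isinstance(spec, ScenarioSpec):
        spec = get_scenario(spec)
    if arm not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    fn = spec.hazard_treated if arm == 1 else spec.hazard_control
    return fn(z)


def true_hr(spec: ScenarioSpec | int, z):
    """True hazard ratio treated/control at biomarker value(s) ``z``."""
    if not isinstance(spec, ScenarioSpec):
        spec = get_scenario(spec)
    return spec.true_hr(z)


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid.

    ``cens_rate`` is the exponential censoring hazard (0.3 -> ~25% censored,
    2 -> ~67% censored under Scenario 1).
    """

    scenario_id: int
    n: int = 250
    cens_rate: float = 0.3
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self):
        get_scenario(self.scenario_id)
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not self.cens_rate > 0:
            raise ValueError("cens_rate must be positive")


def simulate_trial(config: SimulationConfig) -> TrialDataset:
    """Simulate one randomized trial under the configured scenario.

    Subjects get ``Z ~ Uniform(0, 1)`` and a fair-coin arm; the event time is
    exponential with rate ``hazard(Z, arm)``, the censoring time exponential
    with rate ``cens_rate``, and the observed time is the smaller of the two.
    Deterministic given ``config.seed``.
    """
    spec = get_scenario(config.scenario_id)
    rng = np.random.default_rng(config.seed)
    n = config.n
    z = rng.uniform(0.0, 1.0, size=n)
    # open-interval guarantee: log/negative-power transforms need z > 0
    z[z == 0.0] = np.finfo(float).tiny
    arm = rng.integers(0, 2, size=n)
    rate = np.where(arm == 1, spec.hazard_treated(z), spec.hazard_control(z))
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / config.cens_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if arm.min() == arm.max():  # pragma: no cover - probability 2^-(n-1)
        arm[rng.integers(0, n)] ^= 1
    return TrialDataset(z=z, arm=arm, time=time, event=event)
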