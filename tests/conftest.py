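import numpy as np
import pytest

from survinteract import SimulationConfig, TrialDataset, simulate_trial


def make_trial(scenario, n, cens_rate, seed):
    return simulate_trial(
        SimulationConfig(scenario_id=scenario, n=n, cens_rate=cens_rate, seed=seed)
    )


@pytest.fixture
def toy_dataset():
    """Hand-built 8-subject trial, tie-free, events in both arms."""
    return TrialDataset(
        z=np.array([0.10, 0.25, 0.35, 0.45, 0.55, 0.70, 0.85, 0.95]),
        arm=np.array([0, 1, 0, 1, 0, 1, 0, 1]),
        time=np.array([1.3, 0.8, 2.1, 0.5, 3.0, 1.1, 0.9, 2.6]),
        event=np.array([1, 1, 0, 1, 1, 1, 1, 0]),
    )


@pytest.fixture
def medium_trial():
    """One moderately sized simulated trial under the linear-interaction scenario."""
    return make_trial(3, 200, 0.3, seed=42)


def brute_force_partial_loglik(time, event, X, beta, weights=None):
    """Independent O(n^2) Breslow log partial likelihood (oracle; no shared
    code with the package's engine)."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    X = np.atleast_2d(np.asarray(X, float))
    beta = np.asarray(beta, float)
    w = np.ones(len(time)) if weights is None else np.asarray(weights, float)
    eta = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += w[i] * (eta[i] - np.log(np.sum(w[risk] * np.exp(eta[risk]))))
    return ll
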