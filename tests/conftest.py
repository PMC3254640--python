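import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lvcoex as lx

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    return lx.ExperimentDesign()


@pytest.fixture(scope="session")
def consumer_design():
    """Design without the bacteria-only treatment (most estimator tests)."""
    return lx.ExperimentDesign(treatments=("species1_alone", "species2_alone", "both"))


@pytest.fixture(scope="session")
def noiseless_table(consumer_design):
    return lx.generate_experiment(
        consumer_design, lx.GeneratorParams(obs_noise=False, seed=0)
    )


@pytest.fixture(scope="session")
def noisy_table(design):
    return lx.generate_experiment(design, lx.GeneratorParams(seed=7))


def logistic_with_dilutions(r, K, n0, days, event_days, factor):
    """Analytic logistic solution with discrete dilutions, sampled just
    before each event; independent oracle for the ODE path."""
    out = []
    t_prev, n = 0.0, n0
    events = iter(sorted(event_days))
    next_event = next(events, None)
    for t in days:
        # advance through events strictly before t
        while next_event is not None and next_event < t:
            n = _logistic(r, K, n, next_event - t_prev) * factor
            t_prev = next_event
            next_event = next(events, None)
        val = _logistic(r, K, n, t - t_prev)
        out.append(val)  # pre-dilution sample
        if next_event is not None and next_event == t:
            n = val * factor
            t_prev = t
            next_event = next(events, None)
    return np.array(out)


def _logistic(r, K, n0, dt):
    if n0 == 0:
        return 0.0
    return K / (1.0 + (K - n0) / n0 * np.exp(-r * dt))
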