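import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitid as g

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def population():
    """Five reproducible synthetic subjects."""
    return g.make_population(5, seed=11)


@pytest.fixture(scope="session")
def noise_free_session():
    """Factory: a noise-free session of one subject at a chosen cycle frequency."""

    def make(fcycle=1.0, duration=35.0, rest=5.0, seed=0, rotation=None):
        prof = g.make_population(2, seed=3)[0]
        prof.fcycle = fcycle
        prof.noise_sd = {"acc": 0.0, "gyro": 0.0}
        spec = g.SessionSpec(
            duration=duration, rest_seconds=rest, seed=seed,
            rotation=np.eye(3) if rotation is None else rotation)
        return prof, spec, g.simulate_session(prof, spec)

    return make


@pytest.fixture(scope="session")
def reference_resultant(noise_free_session):
    """Band-passed ankle-accelerometer resultant of a noise-free 1 Hz walk."""
    prof, spec, recs = noise_free_session(fcycle=1.0)
    cal = g.calibrate_rest_bias(recs[(1, "acc")])
    return g.bandpass(g.resultant_of(cal))


def synthetic_scores(seed, M=10, N=10, T=400, sep=2.5, noise_lo=0.8,
                     noise_hi=2.8):
    """Log-softmax score tensors from N sources of unequal quality.

    Source i sees the true one-hot logits (scaled by ``sep``) corrupted by
    Gaussian noise whose scale grows linearly from ``noise_lo`` to
    ``noise_hi`` across sources, then normalized to log-posteriors.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, M + 1), T // M)
    noise = np.linspace(noise_lo, noise_hi, N)
    S = np.zeros((len(labels), N, M))
    onehot = labels[:, None] == np.arange(1, M + 1)[None, :]
    for i in range(N):
        logits = sep * onehot + rng.normal(0, noise[i], (len(labels), M))
        S[:, i, :] = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return g.ScoreTensor(scores=S, labels=labels)
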