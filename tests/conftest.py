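import numpy as np
import pytest

from lrlds import ClassSpec, SimConfig, simulate_epochs, two_class_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs():
    """Ten two-class trials at the benchmark study conditions."""
    return simulate_epochs(two_class_config(seed=7), trials_per_class=5)


@pytest.fixture
def fourclass_epochs():
    """Four classes with distinct pole radii, for multiclass checks."""
    specs = [
        ClassSpec(radii=[r] * 2, freqs_hz=[10.0, 22.0], label=i)
        for i, r in enumerate([0.4, 0.6, 0.8, 0.95])
    ]
    cfg = SimConfig(m=8, tau=200, class_specs=specs, obs_snr_db=15.0, seed=11)
    return simulate_epochs(cfg, trials_per_class=8)


def random_stable_model(rng, m=8, n=3, fs=100.0, radius_range=(0.5, 0.95)):
    """Random stable generator: rotation blocks (+ a real pole when n is odd)."""
    from lrlds import make_class_model

    radii = list(rng.uniform(*radius_range, n // 2))
    freqs = list(rng.uniform(5.0, 30.0, n // 2))
    if n % 2:
        radii.append(rng.uniform(*radius_range))
        freqs.append(0.0)
    spec = ClassSpec(radii=radii, freqs_hz=freqs)
    return make_class_model(spec, m, fs, seed=int(rng.integers(2**31)))


def deterministic_trial(model, tau, rng):
    """Noise-free trajectory ``Y = C X`` with ``X(t+1) = A X(t)`` exactly."""
    n = model.A.shape[0]
    x = rng.standard_normal(n)
    X = np.empty((n, tau))
    for t in range(tau):
        X[:, t] = x
        x = model.A @ x
    return model.C @ X, X
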