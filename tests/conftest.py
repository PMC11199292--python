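import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import microtrait as mt

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage64():
    return mt.make_montage(64)


@pytest.fixture(scope="session")
def montage16():
    return mt.make_montage(16)


@pytest.fixture(scope="session")
def proto4(montage64):
    return mt.canonical_maps(montage64)


@pytest.fixture(scope="session")
def short_recording(montage64):
    """One noiseless-ish 20 s subject reused by several preprocessing tests."""
    return mt.simulate_recording(montage64, record_seconds=20.0, snr=10.0, seed=7)


def orthogonal_generators(K: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Random zero-mean, mutually orthogonal unit maps (test helper)."""
    from microtrait.maps import zero_mean

    gens = []
    while len(gens) < K:
        v = zero_mean(rng.normal(size=n_channels))
        for g in gens:
            v -= (v @ g) * g
        n = np.linalg.norm(v)
        if n > 1e-9:
            gens.append(v / n)
    return np.stack(gens)
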