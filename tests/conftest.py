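import numpy as np
import pytest

from mirnoise import ModelParams, NoiseSpec, default_noise, default_params


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """The shipped default scenario (bistable at kappa=7, Gamma=0.5)."""
    return default_params()


@pytest.fixture(scope="session")
def noise() -> NoiseSpec:
    return default_noise()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_stable_points(rng, n, params):
    """Sample n (params, stable Equilibrium) pairs from the scanned ranges."""
    from mirnoise import steady_states

    out = []
    while len(out) < n:
        pt = params.with_(
            alpha=float(rng.uniform(0.01, 0.15)),
            kappa=float(rng.uniform(0.0, 10.0)),
            Gamma=float(rng.uniform(0.0, 2.5)),
            epsilon=float(rng.uniform(0.1, 1.0)),
            k3=float(rng.uniform(2.0, 5.0)),
        )
        stable = [e for e in steady_states(pt) if e.stable]
        if not stable:
            continue
        out.append((pt, stable[int(rng.integers(len(stable)))]))
    return out
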