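import warnings

import numpy as np
import pytest

from calyximg import synthetic_data as sd


@pytest.fixture(autouse=True)
def _quiet_boundary_warnings():
    """Segment-boundary candidate drops are expected on random traces."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="dropped .* candidate", category=UserWarning
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """A small noiseless, eventless configuration."""
    return sd.SimulationConfig(
        spont_rate_hz=0.0,
        noise_sd_pct=0.0,
        bleach_tau_s=np.inf,
        segment_durations_s={
            "pre": 30.0, "ctx": 27.0, "pos": 30.0, "vds": 30.0,
            "posvds": 30.0, "mec": 20.0,
        },
    )


def random_trace(rng, n, kind):
    """Heterogeneous random %ΔF/F-like traces for oracle-equivalence tests."""
    if kind == "noise":
        return rng.normal(0.0, rng.uniform(0.05, 0.5), n)
    if kind == "walk":
        return np.cumsum(rng.normal(0.0, 0.1, n))
    if kind == "events":
        v = rng.normal(0.0, 0.1, n)
        k = sd.make_kernel(2, 0.5, rng.uniform(0.5, 2.0), 20.0)
        for f in rng.integers(0, max(n - 5, 1), size=rng.integers(1, 5)):
            stop = min(f + k.size, n)
            v[f:stop] += k[: stop - f]
        return v
    if kind == "sine":
        t = np.arange(n) / 20.0
        return np.sin(2 * np.pi * rng.uniform(0.2, 2.0) * t) + rng.normal(0, 0.05, n)
    raise ValueError(kind)
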