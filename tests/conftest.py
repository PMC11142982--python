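import numpy as np
import pytest

import oriquant as oq


@pytest.fixture(scope="session")
def default_phantom():
    """One default infarcted-heart phantom with ground truth (seed 0)."""
    spec = oq.PhantomSpec(rng_seed=0)
    volume, labels, ox = oq.generate_heart_phantom(spec)
    return spec, volume, labels, ox


@pytest.fixture(scope="session")
def wavelength_axis():
    return np.arange(500.0, 731.0, 5.0)


@pytest.fixture(scope="session")
def endmembers(wavelength_axis):
    return oq.builtin_endmembers(wavelength_axis)


def mixture_frequency_histogram(seed, n=100_000, w=(0.3, 0.7), mu=(0.25, 0.65),
                                sd=(0.07, 0.10), bins=256):
    """Frequency histogram of n draws from a two-Gaussian mixture on [0, 1]
    (draws outside the unit interval rejected, matching the truncated model)."""
    rng = np.random.default_rng(seed)
    pick = rng.random(n) < w[1]
    x = np.where(pick, rng.normal(mu[1], sd[1], n), rng.normal(mu[0], sd[0], n))
    x = x[(x >= 0) & (x <= 1)]
    counts, edges = np.histogram(x, bins=bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return oq.FrequencyHistogram(centers, counts / counts.sum())
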