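"""Shared fixtures: small synthetic cohorts and random histogram factories."""

from __future__ import annotations

import numpy as np
import pytest

from octarep.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down cohort for fast unit tests (256 px, 4 eyes)."""
    return SimulationConfig(image_size_px=256, n_healthy=2, n_pathology=2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def random_histogram(rng: np.random.Generator, kind: str = "bimodal") -> np.ndarray:
    """Random 256-bin histograms resembling vessel/background grey mixtures.

    ``bimodal`` draws two Gaussian populations plus a uniform floor (the
    image class the thresholding algorithms are designed for); ``uniform``
    draws i.i.d. counts over a random populated range.
    """
    h = np.zeros(256, dtype=np.int64)
    if kind == "uniform":
        lo = int(rng.integers(0, 100))
        hi = int(rng.integers(lo + 20, 256))
        h[lo:hi] = rng.integers(0, 200, hi - lo)
        if h.sum() == 0:
            h[lo] = 1
        return h
    m0 = rng.uniform(20, 90)
    m1 = rng.uniform(120, 220)
    s0 = rng.uniform(5, 25)
    s1 = rng.uniform(10, 40)
    w = rng.uniform(0.3, 0.8)
    n = 20000
    samples = np.concatenate(
        [
            rng.normal(m0, s0, int(w * n)),
            rng.normal(m1, s1, n - int(w * n)),
            rng.uniform(0, 255, 500),
        ]
    )
    vals = np.clip(np.rint(samples), 0, 255).astype(int)
    np.add.at(h, vals, 1)
    return h
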