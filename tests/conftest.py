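"""Shared fixtures: small seeded simulations of the benchmark system."""

from __future__ import annotations

import numpy as np
import pytest

import tvmvar
from tvmvar.bench import make_noise_source


@pytest.fixture(scope="session")
def bench_truth_short():
    """Benchmark coefficient trajectory, 5 s at 1 kHz."""
    return tvmvar.benchmark_trajectory(n_samples=5000, fs=1000.0)


@pytest.fixture(scope="session")
def gaussian_series_short(bench_truth_short):
    """One Gaussian-noise realization of the 5 s benchmark."""
    return tvmvar.simulate_mvar(
        bench_truth_short, make_noise_source("gaussian"), fs=1000.0, seed=11
    )


@pytest.fixture(scope="session")
def static_ar2_series():
    """Single-channel static AR(2) with coefficients (1.58, -0.96),
    unit Gaussian noise, 5000 samples."""
    T = 5000
    coeffs = np.zeros((T, 2, 1, 1))
    coeffs[:, 0, 0, 0] = 1.58
    coeffs[:, 1, 0, 0] = -0.96
    truth = tvmvar.CoefficientTrajectory(coeffs)
    ts = tvmvar.simulate_mvar(
        truth, tvmvar.NoiseSource(kind="gaussian", variance=1.0), fs=1000.0, seed=21
    )
    return truth, ts
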