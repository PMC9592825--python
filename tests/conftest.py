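"""Shared fixtures: synthetic acquisitions generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from sstmon.features import extract_features
from sstmon.io import Acquisition, ProfileSpectrum
from sstmon.registry import default_registry
from sstmon.simulate import ChronogramConfig, SpectrumTruth, simulate_acquisition


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def compact_chron():
    return ChronogramConfig.compact()


@pytest.fixture(scope="session")
def noiseless_acq(registry, compact_chron):
    """Noiseless, baseline-free acquisition: closed-form oracle territory."""
    truth = SpectrumTruth.default(
        registry,
        noise_scale=0.0,
        seed=7,
        baseline_levels=(0.0,) * 9,
        contaminants=(),
    )
    truth.detector_noise_scale = 0.0
    acq, truth = simulate_acquisition(
        truth=truth, registry=registry, chron=compact_chron, run_id="noiseless"
    )
    return acq, truth


@pytest.fixture(scope="session")
def noisy_acq(registry, compact_chron):
    """Realistic acquisition: baseline, contaminants, detector noise."""
    truth = SpectrumTruth.default(registry, seed=3)
    acq, truth = simulate_acquisition(
        truth=truth, registry=registry, chron=compact_chron, run_id="noisy"
    )
    return acq, truth


@pytest.fixture(scope="session")
def noiseless_fv(noiseless_acq, registry):
    acq, _truth = noiseless_acq
    return extract_features(acq, registry)


@pytest.fixture(scope="session")
def noisy_fv(noisy_acq, registry):
    acq, _truth = noisy_acq
    return extract_features(acq, registry)


def gaussian_spectrum(
    mu: float = 305.0968,
    sigma: float = 0.01,
    height: float = 1.0e6,
    span: float = 2.0,
    step: float = 1.0e-3,
    baseline: float = 0.0,
    scan_index: int = 0,
) -> ProfileSpectrum:
    """A single noiseless Gaussian peak on a symmetric uniform grid."""
    n = int(span / step)
    x = mu + np.arange(-n, n + 1) * step
    y = baseline + height * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return ProfileSpectrum(scan_index=scan_index, mz=x, intensity=y)


@pytest.fixture
def simple_acquisition():
    """Tiny 5-scan acquisition with arbitrary profile data for I/O tests."""
    rng = np.random.default_rng(42)
    spectra = []
    for i in range(5):
        mz = np.sort(rng.uniform(100, 1000, 50))
        mz += np.arange(50) * 1e-6  # enforce strict monotonicity
        spectra.append(
            ProfileSpectrum(
                scan_index=i, mz=mz, intensity=rng.uniform(0, 1e5, 50),
                scan_time=float(i),
            )
        )
    return Acquisition(spectra=spectra, run_id="tiny")
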