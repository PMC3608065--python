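import numpy as np
import pytest

from isopick.calibration import ShapeParamModel
from isopick.peakshape import PeakShapeParams, Spectrum


@pytest.fixture
def gauss_model():
    """Constant Gaussian shape model with sigma = 0.05 Th."""
    return ShapeParamModel.constant("gaussian", PeakShapeParams(sigma=0.05))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gaussian_spectrum(centers, heights, sigma, lo, hi, spacing, baseline=0.0):
    """Direct sum of unit-height Gaussians on a regular grid (no templates)."""
    x = np.arange(lo, hi + spacing / 2, spacing)
    y = np.full_like(x, float(baseline))
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return Spectrum(x, y)


@pytest.fixture
def five_pattern_spectrum():
    """Noise-free five-pattern simulation (charges 1-3) with a small
    constant baseline, shared by pipeline-level tests."""
    from isopick.synthetic import GroundTruthPattern, simulate_spectrum

    patterns = [
        GroundTruthPattern(charge=1, height=1.0, mass=799.5),
        GroundTruthPattern(charge=1, height=0.6, mass=1035.3),
        GroundTruthPattern(charge=2, height=0.8, mass=1600.8),
        GroundTruthPattern(charge=2, height=0.4, mass=1850.2),
        GroundTruthPattern(charge=3, height=0.5, mass=2699.7),
    ]
    return simulate_spectrum(
        patterns,
        (750.0, 1050.0),
        spacing=0.06,
        params=PeakShapeParams(sigma=0.15),
        baseline=0.005,
        seed=1,
    )
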