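import numpy as np
import pytest

from icgfa import (
    KineticParams,
    MatchConfig,
    PerfusionCurve,
    PhantomSpec,
    PreprocessConfig,
    ReferenceProfile,
    gamma_variate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_10hz():
    """Uniform 10 Hz time grid over 240 s."""
    return np.arange(2401) / 10.0


@pytest.fixture
def baseline_params():
    return KineticParams()


@pytest.fixture
def reference_curve(grid_10hz, baseline_params):
    """Noise-free normalized baseline curve on the matching grid."""
    return gamma_variate(baseline_params, grid_10hz, source="reference")


@pytest.fixture
def reference_profile(reference_curve):
    return ReferenceProfile(curve=reference_curve)


@pytest.fixture
def fast_match_cfg():
    """Lighter grids than the defaults; keeps the suite inside its budget."""
    return MatchConfig(s_steps=61, tau_step_s=1.0)


@pytest.fixture
def pre_cfg():
    return PreprocessConfig()


@pytest.fixture
def small_phantom_spec():
    """Short, low-rate phantom for fast end-to-end tests."""
    return PhantomSpec(duration_s=240.0, rate_hz=10.0, seed=7)


def dilate_curve(ref: PerfusionCurve, s0: float) -> PerfusionCurve:
    """Time-dilate a curve about t=0, zero outside the recorded domain."""
    vals = np.interp(ref.times_s / s0, ref.times_s, ref.intensities, left=0.0, right=0.0)
    return PerfusionCurve(ref.times_s.copy(), vals, source="determinative")
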