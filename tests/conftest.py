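import numpy as np
import pytest

from cmrquant import GammaVariate, PhantomSpec, TissueTruth, make_phantom, simulate_aif


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Compact phantom used by round-trip tests (annulus ~200 px)."""
    return PhantomSpec(image_size=(48, 48), blood_radius=4, myo_inner_radius=6, myo_outer_radius=10)


@pytest.fixture
def truth() -> TissueTruth:
    return TissueTruth()


@pytest.fixture
def phantom(small_spec, truth):
    return make_phantom(small_spec, truth)


@pytest.fixture
def perf_times() -> np.ndarray:
    """70 heartbeats at RR 0.4 s (HR 150)."""
    return np.arange(70) * 0.4


@pytest.fixture
def aif(perf_times):
    return simulate_aif(GammaVariate(amplitude=1.0, t0=2.0, alpha=2.5, beta=1.5), perf_times)
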