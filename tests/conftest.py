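"""Shared fixtures: phantoms and pipeline runs are expensive, so the
default ones are generated once per session."""

import numpy as np
import pytest

from thoraseg import PhantomSpec, PipelineConfig, generate_phantom, run_mlast


@pytest.fixture(scope="session")
def default_phantom():
    """Default tumor-free 160x160x120 thorax phantom: (spec, volume, labels)."""
    spec = PhantomSpec()
    vol, lab = generate_phantom(spec, seed=1)
    return spec.resolved(), vol, lab


@pytest.fixture(scope="session")
def default_run(default_phantom):
    """Full pipeline run on the default phantom, with intermediates."""
    _, vol, _ = default_phantom
    res, parts = run_mlast(vol, PipelineConfig(), scan_id="default",
                           return_intermediates=True)
    return res, parts


@pytest.fixture(scope="session")
def small_phantom():
    """Fast 96x96x64 phantom for unit tests that need a full anatomy."""
    spec = PhantomSpec(grid_shape=(96, 96, 64))
    vol, lab = generate_phantom(spec, seed=2)
    return spec.resolved(), vol, lab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
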