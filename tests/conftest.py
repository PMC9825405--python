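"""Shared fixtures: reduced-size phantoms and acquisitions generated at
test time (nothing is stored on disk)."""

from __future__ import annotations

import numpy as np
import pytest

from spectoct.config import preset
from spectoct.pipeline import run_pipeline


@pytest.fixture(scope="session")
def smoke_cfg():
    return preset("smoke")


@pytest.fixture(scope="session")
def noiseless_smoke(smoke_cfg):
    """Expectation-mode (noise-free) reduced run: exact Beer-Lambert chain."""
    return run_pipeline(smoke_cfg.replace(expectation=True), write=False)


@pytest.fixture(scope="session")
def noisy_smoke(smoke_cfg):
    """Poisson-sampled reduced run at the default photon budget."""
    return run_pipeline(smoke_cfg, write=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
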