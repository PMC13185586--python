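from __future__ import annotations

import numpy as np
import pytest

from exposeq.barrier import BarrierModel, RegionBarrier, exposure_at_temperature
from exposeq.reference import GenomeReference, Region
from exposeq.simulate import CrosslinkProfile, LibraryParams, simulate_fragments


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def toy_reference():
    """Deterministic 2-segment reference, 300 + 150 nt."""
    gen = np.random.default_rng(99)
    return GenomeReference.random({"RNA1": 300, "RNA2": 150}, gen)


@pytest.fixture(scope="session")
def uniform_profile(toy_reference):
    model = BarrierModel(default_exposure=0.5)
    return exposure_at_temperature(model, toy_reference, 50.0)


@pytest.fixture(scope="session")
def small_run(toy_reference, uniform_profile):
    """2,000 error-free molecules on the toy reference (shared, read-only)."""
    gen = np.random.default_rng(7)
    params = LibraryParams(n_fragments=2000)
    frags = simulate_fragments(
        toy_reference, uniform_profile, CrosslinkProfile.none(), params, "CL-", gen
    )
    return frags, params
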