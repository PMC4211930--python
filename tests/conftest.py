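import numpy as np
import pytest

import odorsearch as osx
from odorsearch.arena import ArenaConfig, run_batch
from odorsearch.plume import get_dose

STIMULATED = ("minimum", "medium", "maximum")


@pytest.fixture(scope="session")
def plume():
    return osx.PlumeParams()


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


@pytest.fixture(scope="session")
def reactive_batches(plume, arena):
    """Reactive trial batches per strategy and dose (150 trials per
    stimulated cell, 60 at no stimulus), shared across tests."""
    out = {}
    for s in ("sp", "za", "ze"):
        for d in STIMULATED:
            out[s, d] = run_batch(s, get_dose(d), plume, arena, 150, seed=2024)
        if s in ("za", "ze"):
            out[s, "none"] = run_batch(s, get_dose("none"), plume, arena, 60,
                                       seed=2024)
    return out


@pytest.fixture(scope="session")
def infotaxis_batch(plume, arena):
    return run_batch("it", get_dose("medium"), plume, arena, 25, seed=2024)


@pytest.fixture(scope="session")
def triphasic_set():
    return osx.gen_triphasic(osx.TriphasicSpec(), seed=11)


@pytest.fixture(scope="session")
def monophasic_set():
    return osx.gen_monophasic(osx.TriphasicSpec(), seed=11)


def successful_lengths(batch):
    return np.array([osx.path_length(t) for t in batch if t.outcome == "success"])
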