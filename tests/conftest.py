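import dataclasses

import numpy as np
import pytest

from avakit.raster import SpikeRaster
from avakit.synth import PRESETS, SimParams, simulate_branching_raster


@pytest.fixture(scope="session")
def sal_raster() -> SpikeRaster:
    """One control-like movie at the default study conditions."""
    return simulate_branching_raster(dataclasses.replace(PRESETS["sal"], seed=11))


@pytest.fixture(scope="session")
def pcp_raster() -> SpikeRaster:
    """One high-persistence movie at the default study conditions."""
    return simulate_branching_raster(dataclasses.replace(PRESETS["pcp"], seed=12))


@pytest.fixture(scope="session")
def small_critical_raster() -> SpikeRaster:
    """A compact near-critical movie for shuffle/avalanche tests."""
    return simulate_branching_raster(
        SimParams(
            n_neurons=200,
            n_frames=20_000,
            offspring_mean=1.0,
            drive_rate=0.05,
            persist_prob=0.0,
            seed=21,
        )
    )


def raster_from_mask(mask, frame_rate=15.0) -> SpikeRaster:
    """Build a unit-amplitude raster from a binary activity pattern."""
    lam = np.asarray(mask, dtype=float)
    return SpikeRaster.from_lambda(lam, frame_rate=frame_rate)
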