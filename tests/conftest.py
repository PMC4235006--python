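import numpy as np
import pytest

from audrf import (
    FRAArchetype,
    RateLevelFunction,
    ResponseGrid,
    StimulusGrid,
    fra_grid,
    noiseless_grid,
)


@pytest.fixture
def tiny_grid():
    """2 frequencies x 2 levels, 1 trial, counts 0..3."""
    grid = StimulusGrid([1000.0, 2000.0], [10.0, 20.0], reference_frequency=1000.0)
    counts = np.array([[[0], [1]], [[2], [3]]])
    return ResponseGrid(grid, counts)


@pytest.fixture
def v_archetype():
    return FRAArchetype(
        "V", cf=2000.0, min_threshold=70.0, slope_low=60.0, slope_high=60.0,
        driven_rate=5.0, spontaneous_rate=0.0,
    )


@pytest.fixture
def v_unit(v_archetype):
    grid = fra_grid(v_archetype.cf)
    return v_archetype, grid, noiseless_grid(v_archetype, grid)


def rlf_from_counts(counts, levels=None, calibration=None):
    """Build an RLF from a per-level list of trial counts (quiet to loud is
    the caller's business; levels are attenuation, increasing)."""
    counts = np.asarray(counts)
    if levels is None:
        levels = 10.0 + 10.0 * np.arange(counts.shape[0])
    return RateLevelFunction(
        frequency=1000.0, levels=np.asarray(levels, dtype=float), counts=counts,
        calibration=calibration, allowed_trials=None,
    )
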