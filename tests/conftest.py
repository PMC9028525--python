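"""Shared fixtures.

The expensive objects (full-size stimulus spec, body set, a complete
closed-loop session) are session-scoped so the end-to-end tests share one
simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from bodybubbles import bubbles as bu
from bodybubbles import synthetic as sy

STIM_WIDTH_PX = 245
STIM_HEIGHT_PX = 310
STIM_WIDTH_DEG = 5.47
STIM_HEIGHT_DEG = 6.90


@pytest.fixture(scope="session")
def full_spec() -> bu.BandSpec:
    """The five-band specification of the full-size stimulus."""
    return bu.band_cutoffs(
        STIM_WIDTH_PX,
        STIM_WIDTH_DEG,
        5,
        height_px=STIM_HEIGHT_PX,
        height_deg=STIM_HEIGHT_DEG,
    )


@pytest.fixture(scope="session")
def small_spec() -> bu.BandSpec:
    """A compact three-band spec for cheap unit tests."""
    return bu.band_cutoffs(128, 4.0, 3)


@pytest.fixture(scope="session")
def bodies() -> list[sy.SyntheticBody]:
    return sy.make_body_set(seed=1)


@pytest.fixture(scope="session")
def part_masks(bodies):
    return {
        k: np.any([b.part_masks[k] for b in bodies], axis=0)
        for k in ("head", "torso_with_arms", "legs")
    }


@pytest.fixture(scope="session")
def planted_emotional_mask(bodies):
    """Union of the planted diagnostic regions of the emotional bodies."""
    return np.any(
        [b.diagnostic_mask for b in bodies if b.emotion != "neutral"], axis=0
    )


@pytest.fixture(scope="session")
def observer(bodies) -> sy.ObserverTemplate:
    return sy.make_observer(bodies, seed=1)


@pytest.fixture(scope="session")
def demo_session(bodies, observer, full_spec):
    """One complete 1920-trial closed-loop session (default observer)."""
    controller = bu.DensityState.uniform(sy.EXPRESSIONS)
    return bu.run_session(bodies, observer, 1920, full_spec, controller, seed=1)
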