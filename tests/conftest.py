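"""Shared fixtures.

Heavy network integrations are session-scoped and reused across the unit
and acceptance tests.  All randomness is seeded; the seeds are part of the
fixture definitions.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sonsim import build_network, make_three_bar_fixture, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Settle length used for segmentation-quality runs: the time-multiplexed
#: group order needs several global-inhibitor cycles to shake out near
#: coincident activations, so traces run until Os completes this many
#: active phases before the readout cycle.
SETTLE_OS_PHASES = 6


@pytest.fixture(scope="session")
def three_bar_trace():
    """Settled 32x32 trace of the documented three-object row pattern."""
    img, gt = make_three_bar_fixture()
    net = build_network(img)
    tr = simulate(net, t_max=60.0, seed=1, record_voltages=False,
                  stop_os_phases=SETTLE_OS_PHASES)
    return img, gt, tr


def quadrant_image(size: int = 32, square: int = 5) -> np.ndarray:
    """Four equal squares, one per quadrant."""
    img = np.zeros((size, size), np.uint8)
    q = size // 2
    off = (q - square) // 2
    for r in (off, q + off):
        for c in (off, q + off):
            img[r:r + square, c:c + square] = 1
    return img


@pytest.fixture(scope="session")
def quadrant_trace():
    """Settled 32x32 trace of the four-quadrant image."""
    img = quadrant_image()
    net = build_network(img)
    tr = simulate(net, t_max=60.0, seed=2, record_voltages=False,
                  stop_os_phases=SETTLE_OS_PHASES)
    return img, tr


@pytest.fixture(scope="session")
def background_trace():
    """Short trace of an all-background image (nothing may oscillate)."""
    img = np.zeros((6, 6), np.uint8)
    net = build_network(img)
    tr = simulate(net, t_max=25.0, seed=3, record_voltages=False,
                  stop_os_phases=4)
    return tr


@pytest.fixture(scope="session")
def single_pixel_trace():
    """1x1 object-pixel network, run long enough for period statistics."""
    net = build_network(np.ones((1, 1), np.uint8))
    tr = simulate(net, t_max=40.0, seed=4, record_voltages=True,
                  stop_os_phases=None)
    return tr


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label maps define the same partition of the foreground
    (label numbering ignored)."""
    fa, fb = np.asarray(a).ravel(), np.asarray(b).ravel()
    fwd: dict = {}
    for x, y in zip(fa, fb):
        if (x == 0) != (y == 0):
            return False
        if x and fwd.setdefault(x, y) != y:
            return False
    inv: dict = {}
    for x, y in fwd.items():
        if inv.setdefault(y, x) != x:
            return False
    return True
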