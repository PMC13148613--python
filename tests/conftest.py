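"""Shared fixtures: grids and small simulated scans (session-scoped)."""

import numpy as np
import pytest

from scansaxs import (default_grid, make_ground_truth, simulate_reduced_scan,
                      analyze_scan)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for I/O round-trip tests (shape checks, not physics)."""
    return default_grid(n_q=64, n_seg=16)


@pytest.fixture(scope="session")
def unprocessed_gt():
    return make_ground_truth("unprocessed", 20, 20, seed=11)


@pytest.fixture(scope="session")
def unprocessed_scan(unprocessed_gt):
    return simulate_reduced_scan(unprocessed_gt, seed=12)


@pytest.fixture(scope="session")
def unprocessed_analysis(unprocessed_scan):
    return analyze_scan(unprocessed_scan)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
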