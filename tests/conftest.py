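"""Shared fixtures: study-condition BEMD runs reused across test modules.

The double-well runs are the expensive shared resource (2e6 steps each); they
are session-scoped and computed once, then inspected by the sampling,
free-energy, reweighting and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from bemd import run_bemd
from bemd.studies import double_well_config, double_well_system

DW_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def dw_system():
    return double_well_system()


@pytest.fixture(scope="session")
def dw_runs(dw_system):
    """Standard double-well BEMD runs (1 biased + 1 neutral), seeds 1..5."""
    return {seed: run_bemd(dw_system, double_well_config(seed)) for seed in DW_SEEDS}


@pytest.fixture(scope="session")
def dw_run(dw_runs):
    return dw_runs[DW_SEEDS[0]]


def tv_distance(samples: np.ndarray, density_fn, lo: float, hi: float,
                n_bins: int = 40) -> float:
    """Total-variation distance between a sample histogram and a density."""
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges)
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    q = density_fn(centers)
    q = q / q.sum()
    return 0.5 * float(np.sum(np.abs(p - q)))
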