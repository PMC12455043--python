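"""Shared fixtures: the default synthetic dataset and its scan results.

The default dataset (seed 1) is expensive enough that the full scan is run
once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from polyscan.config import ScanConfig, SimConfig
from polyscan.model import HaplotypePanel
from polyscan.sim import simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default-parameter synthetic dataset, seed pinned to 1."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def scan_config():
    return ScanConfig(seed=1)


@pytest.fixture(scope="session")
def full_scan(default_sim, scan_config):
    """Complete three-track scan of the default dataset (in memory)."""
    from polyscan.pipeline import run_full_scan

    data = {
        "popmap": default_sim.popmap,
        "layout": default_sim.layout,
        "panels": default_sim.panels,
        "svs": default_sim.svs,
        "strs": default_sim.strs,
        "genes": default_sim.genes,
        "reference": default_sim.reference,
        "accessible": default_sim.accessible,
    }
    return run_full_scan(data, scan_config)


def random_panel(rng, n_hap=8, n_sites=50, length=100_000, chrom="chr1") -> HaplotypePanel:
    """Small random haplotype panel for oracle tests."""
    n_hap = max(4, n_hap - n_hap % 2)
    positions = np.sort(rng.choice(length, size=n_sites, replace=False))
    haps = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    samples = tuple(f"s{i}" for i in range(n_hap // 2))
    return HaplotypePanel(chrom, positions, haps, samples)
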