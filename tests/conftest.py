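"""Shared fixtures: seeded simulated instances and pipeline runs."""

from __future__ import annotations

import pytest

from refchrom.pipeline import PipelineConfig, run_from_sim
from refchrom.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def identity_sim():
    """Zero-rearrangement, zero-chimera instance: 5 x 2 Mb, 40 scaffolds."""
    return simulate(SimConfig(chimera_rate=0.0, n_rearrangements=0, seed=101))


@pytest.fixture(scope="session")
def identity_run(identity_sim):
    return run_from_sim(identity_sim)


@pytest.fixture(scope="session")
def chimera_sim():
    """10% injected chimeras with rearrangements, desk-scale map resolution."""
    return simulate(SimConfig(chimera_rate=0.1, n_rearrangements=4, seed=11,
                              map_resolution=400_000))


@pytest.fixture(scope="session")
def chimera_run(chimera_sim):
    return run_from_sim(chimera_sim)


@pytest.fixture(scope="session")
def calibration_sim():
    """Fewer, larger scaffolds so rearrangement breakpoints fall mid-scaffold
    and the verification stage sees both confirmed and chimeric junctions."""
    return simulate(SimConfig(n_scaffolds=14, min_segment_length=400_000,
                              chimera_rate=0.15, n_rearrangements=5, seed=1,
                              map_resolution=400_000))


@pytest.fixture(scope="session")
def calibration_run(calibration_sim):
    return run_from_sim(calibration_sim)
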