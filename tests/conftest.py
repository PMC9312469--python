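"""Shared fixtures.

The three recovery reports are session-scoped because they dominate the
suite's runtime (tens of replicate simulations each); several tests
assert different properties of the same report.
"""

from __future__ import annotations

import numpy as np
import pytest

from ffskit import DEFAULT_BEAM, SimConfig, SpeciesParams, simulate_trace
from ffskit.experiments import ExperimentConfig, run_experiment


@pytest.fixture(scope="session")
def beam():
    return DEFAULT_BEAM


@pytest.fixture(scope="session")
def solution_report():
    """3D solution-phase diffusion recovery at the reported D."""
    cfg = ExperimentConfig(scenario="solution-3d", replicates=10, base_seed=101)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def membrane_report():
    """2D membrane diffusion recovery at the reported no-Ca value."""
    cfg = ExperimentConfig(scenario="membrane-2d", replicates=10, base_seed=202)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def dimer_report():
    """Monomer/dimer brightness-fraction recovery at the reported F2."""
    cfg = ExperimentConfig(scenario="dimer-mixture", replicates=10, base_seed=303)
    return run_experiment(cfg)


def make_membrane_trace(seed: int, duration: float = 10.0, occupancy: float = 1.0,
                        epsilon: float = 6500.0, d_coeff: float = 6.12):
    """One desk-scale planar-diffusion trace (100 kHz sampling)."""
    beam = DEFAULT_BEAM
    box = (4 * beam.w0, 4 * beam.w0)
    a_box = 4.0 * box[0] * box[1]
    mean_number = occupancy * a_box / beam.psf_integral(2)
    cfg = SimConfig(
        species=(SpeciesParams("m", D=d_coeff, epsilon=epsilon,
                               mean_number=mean_number),),
        beam=beam, dimensionality=2, box_extent=box,
        duration=duration, bin_time=1e-5, seed=seed,
    )
    return cfg, simulate_trace(cfg)


@pytest.fixture(scope="session")
def membrane_trace_bank():
    """Four seeded membrane traces used by estimator and amplitude tests."""
    return [make_membrane_trace(seed) for seed in (11, 22, 33, 44)]
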