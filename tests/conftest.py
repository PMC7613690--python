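"""Shared fixtures.

Simulation-backed fixtures are session-scoped: the reduced-grid families are
the expensive inputs reused across feature, ML, kernel and acceptance tests.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from aistrack.forward_sim import SimulationConfig, discretize, simulate, solve_cable
from aistrack.kernels import build_kernel_library
from aistrack.morphology import AISSpec, assign_biophysics, build_ball_and_stick
from aistrack.pipeline import run_family_footprints
from aistrack.probe import build_probe


@pytest.fixture(scope="session")
def probe():
    return build_probe()


@pytest.fixture(scope="session")
def bas_morphology():
    return assign_biophysics(build_ball_and_stick(AISSpec(15.0)))


@pytest.fixture(scope="session")
def bas_sim(bas_morphology, probe):
    """One default ball-and-stick simulation (d_ais = 15 um) with
    intracellular traces."""
    return simulate(bas_morphology, probe, SimulationConfig(), keep_intracellular=True)


@pytest.fixture(scope="session")
def bas_reduced_footprints():
    """Reduced-grid ball-and-stick family: 24 angles x 2 offsets x 8 AIS
    positions, footprints on the central 12 x 12 block."""
    return run_family_footprints(SimulationConfig.reduced(), "bas")


@pytest.fixture(scope="session")
def kernel_footprints():
    """Finer family used for kernel libraries (7.5 deg, 2.5 um steps)."""
    return run_family_footprints(SimulationConfig.kernel_reduced(), "bas")


@pytest.fixture(scope="session")
def kernel_lib(kernel_footprints):
    return build_kernel_library(kernel_footprints)


@pytest.fixture(scope="session")
def detailed_families():
    """Synthetic-detailed footprint families for the recovery sweep:
    4 soma offsets x 2 rotations, AIS at 5 (baseline) and 7 true positions."""
    cfg = SimulationConfig(
        rotation_step_deg=180.0,
        soma_offsets=((0.0, 0.0), (8.75, 0.0), (0.0, 8.75), (8.75, 8.75)),
        ais_positions=(5, 11, 15, 19, 23, 27, 31, 35, 39),
    )
    fps = run_family_footprints(cfg, "detailed")
    fams = defaultdict(dict)
    for fp in fps:
        fams[(fp.meta["offset"], fp.meta["theta_deg"])][fp.meta["d_ais"]] = fp
    return dict(fams)


@pytest.fixture(scope="session")
def delta_dataset(bas_reduced_footprints):
    """Labeled delta/sham vectors from the reduced family (sham_ratio 1)."""
    from aistrack.features import build_delta_dataset
    from aistrack.pipeline import split_baselines

    baselines, comparisons = split_baselines(bas_reduced_footprints)
    return build_delta_dataset(baselines, comparisons, sham_ratio=1, seed=0)
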