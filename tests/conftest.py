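"""Shared fixtures: small designs and simulated datasets."""

import numpy as np
import pytest

from facereloc import ExperimentConfig, SimParams, build_design, simulate_dataset
from facereloc.simulate import ScanpathParams


@pytest.fixture(scope="session")
def exp1_design():
    """Full Experiment-1 design (256 trials), fixed seed."""
    return build_design(ExperimentConfig.experiment_1(),
                        np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_design():
    """Compact Experiment-1 design (4 trials per cell, 32 trials)."""
    return build_design(ExperimentConfig.experiment_1(reps_per_cell=4),
                        np.random.default_rng(11))


@pytest.fixture(scope="session")
def clean_params():
    """Simulation parameters with every exclusion-event rate at zero."""
    gaze = ScanpathParams(p_skip_face=0.0, p_calib_fail=0.0,
                          p_precheck_fail=0.0, p_center_violation=0.0)
    return SimParams(gaze=gaze)


@pytest.fixture(scope="session")
def small_dataset(small_design, clean_params):
    """4 participants x 32 trials, no exclusion events."""
    return simulate_dataset(small_design, 4, clean_params,
                            np.random.default_rng(23))
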