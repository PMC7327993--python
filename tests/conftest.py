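"""Shared fixtures.

The expensive session fixtures implement the shared-sample design of the
simulation study once: the same 1,000 uniform samples per sample size feed
the cut-off-0 inflation checks, the Z calibration for both suites, and
(via the calibrated table) the power study.
"""

import numpy as np
import pytest

from circaic.calibration import (
    CalibrationEntry,
    CalibrationTable,
    null_delta_aics,
    z_from_null,
)
from circaic.simulation import ExperimentConfig, power_experiment

STUDY_SIZES = (10, 20, 50, 100)
STUDY_REPS = 1_000
STUDY_SEED = 202


@pytest.fixture(scope="session")
def null_study():
    """Null delta-AIC draws for S2 and S10 on shared uniform samples,
    for each study sample size."""
    return {
        n: null_delta_aics(n, ["S2", "S10"], STUDY_REPS, seed=STUDY_SEED)
        for n in STUDY_SIZES
    }


@pytest.fixture(scope="session")
def study_ztable(null_study):
    """Calibration table derived from the shared null draws (alpha 0.05)."""
    table = CalibrationTable()
    for n, draws in null_study.items():
        for suite, d in draws.items():
            table.add(CalibrationEntry(
                n=n, suite_name=suite, alpha=0.05, reps=STUDY_REPS,
                seed=STUDY_SEED, Z=z_from_null(d, 0.05), null_draws=np.sort(d),
            ))
    return table


@pytest.fixture(scope="session")
def vm_power_study(study_ztable):
    """Power of all five tests and the Z-calibrated AIC rules (S2, S10)
    against the von Mises alternative preset."""
    config = ExperimentConfig(
        sample_sizes=STUDY_SIZES,
        reps=STUDY_REPS,
        tests=("rayleigh", "kuiper", "watson", "rao", "hr"),
        suites=("S2", "S10"),
        cutoffs=("Z",),
        alternative="vm",
        seed=303,
        mc_reps=999,
    )
    return power_experiment(config, study_ztable)
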