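"""Shared fixtures.

The default seeded cohort and its phase analysis are expensive (about a
minute together) and session-scoped; everything else is generated per test.
"""
from __future__ import annotations

import numpy as np
import pytest

from artdose.accumulation import analyze_phase
from artdose.config import RunConfig
from artdose.grids import Grid3D, Mask3D
from artdose.synthetic_cohort import generate_cohort


def make_grid(values, spacing=(1.0, 1.0, 1.0)):
    return Grid3D(np.asarray(values, dtype=float), spacing=spacing)


def make_mask(flags, spacing=(1.0, 1.0, 1.0), name="S"):
    return Mask3D(np.asarray(flags, dtype=bool), name=name, spacing=spacing)


@pytest.fixture()
def ramp_100():
    """100-voxel linear ramp 1..100 Gy inside a full mask (shape 1x10x10)."""
    values = np.arange(1.0, 101.0).reshape(1, 10, 10)
    return make_grid(values), make_mask(np.ones((1, 10, 10)))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(RunConfig())


@pytest.fixture(scope="session")
def default_phase_results(default_cohort):
    cfg = default_cohort.config
    results = []
    for phase_id, fractions in default_cohort.phases().items():
        results.append(analyze_phase(
            phase_id, fractions, default_cohort.phantom.ptv,
            cfg.exponents["tumor"], cfg.plan.prescription_gy,
            plan_types=("scheduled", "adaptive")))
    return results
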