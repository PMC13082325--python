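"""Shared fixtures: small study conditions and coarse simulation grids.

Everything is generated programmatically; expensive objects (solved
fields, trained models) are session-scoped so the property suites can
share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from clss.config import SystemConfig
from clss.synthetic import SyntheticSpec
from clss.volume_conductor import ArmModel, ElectrodePatch, solve_potential


@pytest.fixture(scope="session")
def cfg() -> SystemConfig:
    return SystemConfig()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced subject/window counts for fast unit tests."""
    return SyntheticSpec(n_subjects=2, windows_per_class=3)


@pytest.fixture(scope="session")
def coarse_arm() -> ArmModel:
    """Coarse cylindrical grid: fast solves for property tests."""
    return ArmModel(dr_target_mm=2.0, dtheta_deg=10.0, dz_mm=5.0)


def bipolar_pair(arm: ArmModel, voltage: float = 1.0,
                 spacing: float = 75.0, diameter: float = 30.0):
    zm = arm.length_mm / 2
    return [
        ElectrodePatch(size_mm=diameter, center_z_mm=zm - spacing / 2,
                       polarity="cathode", potential_v=-voltage / 2),
        ElectrodePatch(size_mm=diameter, center_z_mm=zm + spacing / 2,
                       polarity="anode", potential_v=+voltage / 2),
    ]


@pytest.fixture(scope="session")
def coarse_field(coarse_arm):
    """Solved +/-0.5 V bipolar pair on the coarse grid."""
    return solve_potential(coarse_arm, bipolar_pair(coarse_arm))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
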