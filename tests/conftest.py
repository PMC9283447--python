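"""Shared synthetic-scenario fixtures (see dryseason.scenarios)."""
from __future__ import annotations

import pytest

from dryseason import scenarios


@pytest.fixture(scope="session")
def sinusoid_config():
    """Mean 3 mm/d, relative amplitude 0.5, rainfall minimum at day 200."""
    return scenarios.sinusoid_config()


@pytest.fixture(scope="session")
def bimodal_config_factory():
    """Two-harmonic rainfall with dry seasons centred in DJF and JJA."""
    return scenarios.bimodal_config


@pytest.fixture(scope="session")
def humid_point():
    """Rainforest-like point: P >> Ep, bucket essentially never stressed."""
    return scenarios.point_with_fluxes(scenarios.humid_config())


@pytest.fixture(scope="session")
def arid_point():
    """Semi-arid point: Ep >> P on average, bucket chronically stressed."""
    return scenarios.point_with_fluxes(scenarios.arid_config())
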