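"""Shared simulation fixtures.

Long stiff integrations are session-scoped so each scenario is simulated
once per run: 5-day control/sham at strict tolerances (reference runs),
a 3-day kindled run, and fast-preset variants used by the calibration and
robustness checks.
"""

import numpy as np
import pytest

import hpaxis


@pytest.fixture(scope="session")
def control5_strict():
    return hpaxis.integrate(hpaxis.control_scenario(days=5))


@pytest.fixture(scope="session")
def sham5_strict():
    return hpaxis.integrate(hpaxis.sham_scenario(days=5))


@pytest.fixture(scope="session")
def lhk3_strict():
    return hpaxis.integrate(hpaxis.lhk_scenario(days=3))


@pytest.fixture(scope="session")
def control5_fast():
    return hpaxis.integrate(hpaxis.control_scenario(days=5).with_tolerances("fast"))


@pytest.fixture(scope="session")
def sham3_fast():
    return hpaxis.integrate(hpaxis.sham_scenario(days=3).with_tolerances("fast"))


@pytest.fixture(scope="session")
def lhk3_fast():
    """Kindled run at the fitted intensity; the data-generating truth for calibration."""
    return hpaxis.integrate(hpaxis.lhk_scenario(days=3, intensity=5e-8).with_tolerances("fast"))


@pytest.fixture(scope="session")
def kindle_start():
    return hpaxis.simulate.clock_to_minutes("21:12", day=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
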