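import warnings

import numpy as np
import pytest

import icekin as ik


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # individual tests assert on errors, not on the advisory warnings the
    # detection chain emits for degenerate geometry
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def sucrose_table():
    return ik.default_sucrose_table()


@pytest.fixture(scope="session")
def default_run():
    """One noisy default-scenario curve plus its ground truth (seed fixed)."""
    return ik.generate_cooling_curve(seed=42)


@pytest.fixture(scope="session")
def noisefree_run():
    scenario = ik.CurveScenario(noise_sigma=0.0)
    return ik.generate_cooling_curve(scenario)


@pytest.fixture
def wsorb():
    """The sorbitol water model system: 300 g sorbitol in 1000 g water."""
    return ik.Formulation(
        (
            ik.Ingredient("water", 1000.0, {"water": 100.0}),
            ik.Ingredient("sorbitol", 300.0, {"sorbitol": 100.0}),
        ),
        name="WSORB",
    )


@pytest.fixture
def wsucr_wsorb():
    """Mixed sugar system: 150 g sucrose + 150 g sorbitol in 1000 g water."""
    return ik.Formulation(
        (
            ik.Ingredient("water", 1000.0, {"water": 100.0}),
            ik.Ingredient("sucrose", 150.0, {"sucrose": 100.0}),
            ik.Ingredient("sorbitol", 150.0, {"sorbitol": 100.0}),
        ),
        name="WSUCR+WSORB",
    )


@pytest.fixture
def linear_curve():
    """Exact chilling line T = 20 - 16 t, 1 Hz over 2 minutes."""
    t = np.arange(0.0, 2.0001, 1 / 60)
    return ik.CoolingCurve(t, 20.0 - 16.0 * t)
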