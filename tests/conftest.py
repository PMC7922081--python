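import numpy as np
import pytest

from insolesim import geometry, layout, synthetic
from insolesim.core import PressureRecording, SensorGeometry


@pytest.fixture(scope="session")
def template_38():
    return synthetic.generate_template("38-39")


@pytest.fixture(scope="session")
def default_layout_38():
    return layout.default_layout("38-39")


@pytest.fixture(scope="session")
def gait_trial():
    """Noise-free 3-step walking trial with analytic ground truth."""
    params = synthetic.TrialParams(task="gait", noise_sd=0.0, n_steps=3, seed=1)
    return synthetic.generate_gait_trial(params)


@pytest.fixture(scope="session")
def drop_trial():
    params = synthetic.TrialParams(task="drop", noise_sd=0.0, seed=2)
    return synthetic.generate_drop_trial(params)


@pytest.fixture(scope="session")
def lifting_trial():
    params = synthetic.TrialParams(task="lifting", noise_sd=0.0, seed=3)
    return synthetic.generate_lifting_trial(params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def recording_factory(template_38):
    """Build a 99-sensor recording from an arbitrary pressure matrix."""

    def make(pressures, sensors=None, fs=100.0, size="38-39", task="gait"):
        sensors = sensors if sensors is not None else template_38
        return PressureRecording(
            sensors=list(sensors),
            pressures=np.asarray(pressures, dtype=float),
            fs=fs,
            insole_size=size,
            side="left",
            task=task,
            total_surface_mm2=geometry.total_surface_mm2(size),
            body_weight_N=675.0,
        )

    return make


@pytest.fixture(scope="session")
def recording_factory_session(template_38):
    """Session-scoped variant for hypothesis-driven tests."""

    def make(pressures, fs=100.0, size="38-39", task="gait"):
        return PressureRecording(
            sensors=list(template_38),
            pressures=np.asarray(pressures, dtype=float),
            fs=fs,
            insole_size=size,
            side="left",
            task=task,
            total_surface_mm2=geometry.total_surface_mm2(size),
            body_weight_N=675.0,
        )

    return make


@pytest.fixture(scope="session")
def sim_setup_session(default_layout_38, template_38):
    from insolesim import simulate

    gmap = simulate.assign_groups(default_layout_38, template_38, k=3)
    return default_layout_38, gmap


@pytest.fixture
def toy_grid():
    """4 x 4 grid of 10 mm cells in the hindfoot band (toy geometry for
    exhaustive oracles)."""
    sensors = []
    sid = 0
    for row in range(4):
        for col in range(4):
            cx = 25.0 + 10.0 * col
            cy = 15.0 + 10.0 * row
            sensors.append(
                SensorGeometry(
                    sensor_id=sid,
                    center_x=cx,
                    center_y=cy,
                    width=10.0,
                    height=10.0,
                    region=geometry.region_of(cx, cy, "38-39"),
                )
            )
            sid += 1
    return sensors
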