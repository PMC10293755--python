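import numpy as np
import pytest

from thermospread import (
    CauteryApplication,
    SensorModel,
    TissueModel,
    compute_pixel_size,
    render_thermograms,
    sequence_from_array,
    simulate_field,
)
from thermospread.cohort import fiducial_spec


@pytest.fixture(scope="session")
def tiny_tissue():
    """A 16×16×8 mm block at 1 mm voxels — fast enough for per-test solves."""
    return TissueModel(dims=(16, 16, 8), voxel_mm=1.0)


@pytest.fixture(scope="session")
def reduced_tissue():
    """The default 30×30×20 mm block at the coarse 1 mm voxel pitch."""
    return TissueModel(dims=(30, 30, 20), voxel_mm=1.0)


@pytest.fixture(scope="session")
def default_tissue():
    return TissueModel()


@pytest.fixture(scope="session")
def sim_field_30w2s(reduced_tissue):
    app = CauteryApplication(power_w=30.0, duration_s=2.0)
    return simulate_field(reduced_tissue, app, t_end_s=3.0, dt_s=0.05, snapshot_every_s=0.1)


@pytest.fixture(scope="session")
def noise_free_sensor():
    return SensorModel(array_shape=(40, 50), netd_c=0.0)


@pytest.fixture(scope="session")
def sim_sequence(sim_field_30w2s, noise_free_sensor):
    """A rendered noise-free 30 W / 2 s sequence (31 frames at 10 Hz)."""
    return render_thermograms(sim_field_30w2s, noise_free_sensor, seed=1)


@pytest.fixture(scope="session")
def unit_calibration(noise_free_sensor):
    fid = fiducial_spec(noise_free_sensor)
    return compute_pixel_size(fid["p1"], fid["p2"], fid["known_length_mm"])


def make_sequence(stack, frame_rate_hz=10.0):
    return sequence_from_array(np.asarray(stack, dtype=float), frame_rate_hz=frame_rate_hz)


@pytest.fixture
def make_seq():
    return make_sequence
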