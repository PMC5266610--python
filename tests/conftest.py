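"""Shared fixtures: reference-acquisition scenarios and rendered ensembles."""
import numpy as np
import pytest

import sweiproc as sw


@pytest.fixture
def phantom_scenario():
    """Elastic-phantom-like scenario: 1.1 m/s, 200 Hz-band Gaussian pulse."""
    return sw.ShearWaveScenario(true_sws=1.1, pulse_center_frequency=200.0,
                                pulse_sigma=1.0e-3, amplitude=5.0e-6,
                                origin_x=0.0, decay_exponent=0.5,
                                start_time=1.5e-3, seed=0)


@pytest.fixture
def phantom_motion(phantom_scenario):
    """Noise-free motion field at 1–4 mm, PRI 0.1 ms, long track window."""
    x = np.arange(1.0e-3, 4.01e-3, 0.5e-3)
    times, labels = sw.frame_schedule(pri=1.0e-4, n_reference=4, n_push=3,
                                      n_track=60)
    return sw.simulate_shear_wave_motion(phantom_scenario, x, times, labels)


@pytest.fixture
def phantom_iq(phantom_motion):
    """Noise-free pure-phase IQ rendering of the phantom motion."""
    speckle = sw.SpeckleConfig(axial_samples=64, axial_interval=74.0e-6,
                               fractional_bandwidth=0.6, snr_db=np.inf, seed=1)
    return sw.render_iq_ensemble(phantom_motion, speckle, fc=5.2e6,
                                 sound_speed=1540.0)


def motion_2d(data, dt, x=None, quantity="displacement"):
    """Small helper to wrap a (lateral, time) array as a MotionField."""
    data = np.asarray(data, dtype=float)
    n_lat, n_t = data.shape
    if x is None:
        x = 1.0e-3 + 1.0e-3 * np.arange(n_lat)
    return sw.MotionField(data=data, quantity=quantity,
                          times=dt * np.arange(n_t), lateral_positions=x)
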