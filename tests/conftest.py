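import numpy as np
import pytest

from dixonperf.phantom import (AifParams, MotionTrajectory, PhantomSpec,
                               make_phantom)


@pytest.fixture(scope="session")
def aif_45s():
    """Main-bolus-like AIF on a 45 s / 1 Hz grid."""
    from dixonperf.kinetics import ConcentrationCurve
    from dixonperf.phantom import gamma_variate_aif
    t = np.arange(0, 45.0)
    v = gamma_variate_aif(AifParams(delay=3.0, amplitude=3.0), t)
    return ConcentrationCurve(t, v, role="aif")


@pytest.fixture(scope="session")
def static_phantom():
    """Small noiseless static phantom with early bolus timing."""
    spec = PhantomSpec(grid_size=64, n_frames=48,
                       aif_params=AifParams(delay=24.0, prebolus_delay=4.0))
    series, truth = make_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def moving_phantom():
    """128x128 noiseless phantom with rigid sinusoidal breathing motion."""
    traj = MotionTrajectory.sinusoidal(40, rot_amplitude_deg=3.0)
    spec = PhantomSpec(grid_size=128, n_frames=40, motion=traj,
                       aif_params=AifParams(delay=20.0, prebolus_delay=4.0))
    series, truth = make_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noisy_moving_phantom():
    """96x96 noisy phantom with rigid + smooth non-rigid motion."""
    traj = MotionTrajectory.sinusoidal(48, nonrigid_amplitude=1.5)
    spec = PhantomSpec(grid_size=96, n_frames=48, motion=traj, noise_sd=0.02,
                       seed=11, aif_params=AifParams(delay=24.0, prebolus_delay=4.0))
    series, truth = make_phantom(spec)
    return spec, series, truth
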