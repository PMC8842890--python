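import numpy as np
import pytest

from pendulearn.pendulum import PendulumParams, PendulumTrace, PivotTrajectory


@pytest.fixture
def params():
    return PendulumParams()


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def make_sine_block(freq_hz: float, offset_rad: float, fs: float = 100.0,
                    duration: float = 30.0, ball_amp: float = 0.1):
    """Synthetic block whose ball velocity lags the pivot velocity by
    ``offset_rad``.

    The pivot's horizontal velocity is sin(2*pi*f*t); the pendulum states are
    constructed so the ball's relative horizontal velocity l*theta_dot*cos(theta)
    approximates ball_amp*sin(2*pi*f*t - offset) (small angles, cos(theta)~1).
    """
    from pendulearn.records import BlockRecording, Modality

    p = PendulumParams()
    n = int(round(fs * duration)) + 1
    t = np.arange(n) / fs
    w = 2 * np.pi * freq_hz
    y_dot = np.sin(w * t)
    y = -np.cos(w * t) / w
    theta_dot = ball_amp * np.sin(w * t - offset_rad) / p.l
    theta = -ball_amp * np.cos(w * t - offset_rad) / (p.l * w)
    zeros = np.zeros(n)
    pivot = PivotTrajectory(t, y, zeros, y_dot, zeros,
                            w * np.cos(w * t), zeros)
    trace = PendulumTrace(t, theta, theta_dot)
    return BlockRecording(modality=Modality(True, False), phase_label="BL",
                          rod_length=p.l, pivot=pivot, states=trace), p
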