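"""Per-block outcome metrics: phase synchrony, variability, effort.

The movement phase difference quantifies whether the pivot (hand) leads the
pendulum ball.  Both the pivot's horizontal velocity and the ball's relative
horizontal velocity (l*theta_dot*cos(theta)) are nearly cyclic during
swing-up; each is band-pass filtered (2nd-order Butterworth, 0.5-10 Hz,
applied forward-backward so the filter itself adds no phase), normalised to
zero mean / unit SD, and converted to an instantaneous phase with the Hilbert
transform.  The metric is the mean per-sample phase difference
phi_pivot - phi_ball, wrapped to (-pi, pi]; positive = the pivot leads.

Only the portion of the block before the first inversion onset is analysed
(the whole block if the pendulum is never inverted): once inverted the motion
is a hold, not a cyclic swing, and would bias the phase estimate.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .exceptions import DegenerateSignalError, InsufficientDataError
from .pendulum import (PendulumParams, PendulumTrace, PivotTrajectory,
                       compute_score, wrap_angle)
from .records import BlockRecording, OutcomeMetrics

__all__ = [
    "bandpass",
    "instantaneous_phase",
    "movement_phase_difference",
    "movement_variability",
    "physical_effort",
    "block_metrics",
]

BAND_LOW_HZ = 0.5
BAND_HIGH_HZ = 10.0
MIN_PHASE_WINDOW_S = 2.0


def bandpass(signal, fs: float, low: float = BAND_LOW_HZ,
             high: float = BAND_HIGH_HZ, order: int = 2) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass (default 0.5-10 Hz).

    Applied forward-backward (``filtfilt``) so the pass band keeps zero phase
    shift; the effective magnitude response is squared.
    """
    if fs <= 2.0 * high:
        raise ValueError(
            f"sample rate {fs} Hz too low for a {high} Hz upper cut-off")
    signal = np.asarray(signal, dtype=float)
    b, a = butter(order, [low, high], btype="bandpass", fs=fs)
    return filtfilt(b, a, signal)


def instantaneous_phase(signal) -> np.ndarray:
    """Unwrapped analytic-signal phase of a normalised signal (rad).

    The signal is normalised internally to zero mean and unit SD, so the
    phase is invariant to amplitude scaling and offsets.
    """
    signal = np.asarray(signal, dtype=float)
    sd = np.std(signal)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("constant signal has no phase")
    normalised = (signal - np.mean(signal)) / sd
    return np.unwrap(np.angle(hilbert(normalised)))


def _phase_window(trace: PendulumTrace, params: PendulumParams,
                  mask_mode: str) -> np.ndarray:
    """Boolean mask of the samples entering the phase analysis."""
    from .pendulum import inversion_mask

    inv = inversion_mask(trace, params)
    if mask_mode == "pre_first_inversion":
        idx = np.flatnonzero(inv)
        mask = np.ones(len(trace), dtype=bool)
        if idx.size:
            mask[idx[0]:] = False
        return mask
    if mask_mode == "not_inverted":
        return ~inv
    raise ValueError(f"unknown mask_mode {mask_mode!r}")


def movement_phase_difference(block: BlockRecording, params: PendulumParams,
                              mask_mode: str = "pre_first_inversion",
                              average: str = "arithmetic") -> float:
    """Mean pivot-vs-ball phase difference of one block (rad).

    Positive values mean the pivot leads the ball.  ``mask_mode`` selects
    which samples are analysed: the prefix of the block before the first
    inversion onset (default) or all non-inverted samples.  ``average`` is
    the arithmetic mean of per-sample wrapped differences (default) or the
    circular mean.
    """
    pivot, trace = block.pivot, block.states
    fs = pivot.sample_rate
    mask = _phase_window(trace, params, mask_mode)
    if mask.sum() * pivot.dt < MIN_PHASE_WINDOW_S:
        raise InsufficientDataError(
            "pre-inversion window shorter than "
            f"{MIN_PHASE_WINDOW_S} s; cannot estimate phases")
    if mask_mode == "pre_first_inversion":
        sl = slice(0, int(mask.sum()))
        v_pivot = pivot.y_dot[sl]
        v_ball = (params.l * trace.theta_dot * np.cos(trace.theta))[sl]
    else:
        v_pivot = pivot.y_dot[mask]
        v_ball = (params.l * trace.theta_dot * np.cos(trace.theta))[mask]
    phi_pivot = instantaneous_phase(bandpass(v_pivot, fs))
    phi_ball = instantaneous_phase(bandpass(v_ball, fs))
    diff = wrap_angle(phi_pivot - phi_ball)
    if average == "arithmetic":
        return float(np.mean(diff))
    if average == "circular":
        return float(np.angle(np.mean(np.exp(1j * diff))))
    raise ValueError(f"unknown average {average!r}")


def movement_variability(pivot: PivotTrajectory) -> tuple[float, float]:
    """Sample SD of the pivot position in y (horizontal) and z (vertical)."""
    if len(pivot) == 0:
        raise ValueError("empty trajectory")
    ddof = 1 if len(pivot) > 1 else 0
    return (float(np.std(pivot.y, ddof=ddof)),
            float(np.std(pivot.z, ddof=ddof)))


def physical_effort(torques) -> float:
    """Time-average Euclidean norm of the generated joint-torque series."""
    torques = np.atleast_2d(np.asarray(torques, dtype=float))
    if torques.size == 0:
        raise ValueError("empty torque series")
    return float(np.mean(np.linalg.norm(torques, axis=1)))


def block_metrics(block: BlockRecording, params: PendulumParams,
                  mask_mode: str = "pre_first_inversion") -> OutcomeMetrics:
    """All outcome metrics of one block.

    The phase difference is ``None`` when the analysable window is too short;
    effort is ``None`` when the block carries no torque series.
    """
    score = block.score
    if score is None:
        score = compute_score(block.states, params).score
    try:
        phase = movement_phase_difference(block, params, mask_mode=mask_mode)
    except (InsufficientDataError, DegenerateSignalError):
        phase = None
    var_y, var_z = movement_variability(block.pivot)
    effort = physical_effort(block.torques) if block.torques is not None else None
    return OutcomeMetrics(score=score, phase_diff=phase, var_y=var_y,
                          var_z=var_z, effort=effort)
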