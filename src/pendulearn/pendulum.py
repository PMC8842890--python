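"""Virtual pendulum dynamics, haptic rod force, and the inversion score.

The task object is a single-DoF pendulum whose pivot is moved by the user in
the vertical (y, z) plane.  With ``theta`` the pendulum angle (0 = hanging
straight down, pi = inverted, positive counter-clockwise, z up), the angular
acceleration is

    theta_dd = -(1/l) * (y_dd*cos(theta) + (z_dd + g)*sin(theta))
               - c/(m*l**2) * theta_d

where (y_dd, z_dd) is the pivot acceleration, g the (reduced) gravity acting
on the virtual pendulum, and c a small rotational damping.  The force felt
along the rod at the pivot is

    F_rod = m * (theta_d**2 * l - y_dd*sin(theta) + (g + z_dd)*cos(theta))

and the score accrues at rate k*(angle_tol - |theta - pi|) whenever the
pendulum is within ``angle_tol`` of upright and slower than ``speed_tol``.

Integration uses a fixed-step classical Runge-Kutta (RK4) scheme with the
pivot acceleration held constant over each sample interval, mirroring a
discrete-time real-time loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidStateError

__all__ = [
    "EARTH_GRAVITY",
    "PendulumParams",
    "PendulumState",
    "PivotTrajectory",
    "PendulumTrace",
    "ScoreResult",
    "step_dynamics",
    "simulate_block",
    "rod_force",
    "decompose_rod_force",
    "compute_score",
    "wrap_angle",
]

#: Earth gravity used throughout (m/s^2); the virtual pendulum sees a fraction
#: of it, the human arm the full value.
EARTH_GRAVITY = 9.81

#: Default real-time loop rate of the haptic simulation (Hz).
DEFAULT_SAMPLE_RATE = 3000.0


def wrap_angle(theta):
    """Wrap angle(s) onto (-pi, pi]."""
    wrapped = np.mod(-np.asarray(theta) + np.pi, 2.0 * np.pi)
    return -(wrapped - np.pi)


@dataclass(frozen=True)
class PendulumParams:
    """Physical constants of the virtual pendulum and its score.

    Parameters
    ----------
    m : float
        Pendulum (ball) mass in kg.  A heavy ball makes the velocity and
        acceleration dependent interaction forces salient.
    l : float
        Rod length in m.  0.35 m for the main task, 0.25 m for the transfer
        task (higher natural frequency, hence different dynamics).
    c : float
        Rotational damping in N*m*s/rad, required to stabilise the rendered
        pendulum.
    g : float
        Gravity acting on the virtual pendulum, m/s^2.  Reduced to 25% of
        earth gravity so the heavy ball stays manageable.
    k : float
        Score gain in points/(rad*s).
    angle_tol : float
        Half-width of the inversion window around theta = pi (rad).
    speed_tol : float
        Angular-speed bound of the inversion window (rad/s).
    """

    m: float = 2.5
    l: float = 0.35
    c: float = 0.16
    g: float = 0.25 * EARTH_GRAVITY
    k: float = 19.0
    angle_tol: float = math.pi / 6
    speed_tol: float = math.pi / 3

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.l > 0 and self.k > 0):
            raise ValueError("m, l and k must be positive")
        if self.c < 0 or self.g < 0:
            raise ValueError("c and g must be non-negative")
        if not (0 < self.angle_tol < math.pi):
            raise ValueError("angle_tol must lie in (0, pi)")
        if self.speed_tol <= 0:
            raise ValueError("speed_tol must be positive")

    @classmethod
    def transfer(cls, **overrides) -> "PendulumParams":
        """Parameters of the transfer task (shorter rod, 0.25 m)."""
        overrides.setdefault("l", 0.25)
        return cls(**overrides)

    @property
    def natural_frequency(self) -> float:
        """Small-angle natural frequency sqrt(g/l) in rad/s."""
        return math.sqrt(self.g / self.l)

    def energy(self, theta, theta_dot):
        """Mechanical energy for a stationary pivot (J), zero at the hang."""
        return 0.5 * self.m * self.l**2 * np.asarray(theta_dot) ** 2 + (
            self.m * self.g * self.l * (1.0 - np.cos(theta))
        )


@dataclass(frozen=True)
class PendulumState:
    """Pendulum state at one instant.

    ``theta`` is stored unwrapped (continuous across revolutions); use
    :attr:`theta_wrapped` for the (-pi, pi] view.
    """

    t: float
    theta: float
    theta_dot: float

    @property
    def theta_wrapped(self) -> float:
        return float(wrap_angle(self.theta))


def _uniform_dt(t: np.ndarray, tol: float = 1e-9) -> float:
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("time axis needs at least two samples")
    if np.any(dt <= 0):
        raise ValueError("time axis must be strictly increasing")
    if np.ptp(dt) > tol:
        raise ValueError("time axis must be uniformly sampled")
    return float(np.mean(dt))


@dataclass
class PivotTrajectory:
    """Pivot (hand-module) path in the vertical plane with derivatives.

    All series share one uniform time axis.  If only positions are supplied
    use :meth:`from_positions`, which reconstructs velocities and
    accelerations by second-order central differences (one-sided at the
    ends).
    """

    t: np.ndarray
    y: np.ndarray
    z: np.ndarray
    y_dot: np.ndarray
    z_dot: np.ndarray
    y_ddot: np.ndarray
    z_ddot: np.ndarray
    dt: float = field(init=False)

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "y", "z", "y_dot", "z_dot", "y_ddot", "z_ddot"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        n = arrays["t"].size
        if any(a.size != n for a in arrays.values()):
            raise ValueError("all trajectory series must have equal length")
        if not all(np.all(np.isfinite(a)) for a in arrays.values()):
            raise InvalidStateError("trajectory contains non-finite values")
        self.dt = _uniform_dt(arrays["t"])

    def __len__(self) -> int:
        return self.t.size

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @classmethod
    def from_positions(cls, t, y, z) -> "PivotTrajectory":
        """Build a trajectory from positions only.

        Velocities/accelerations are computed with ``np.gradient``
        (second-order central differences, second-order one-sided ends).
        """
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        dt = _uniform_dt(t)
        edge = 2 if t.size > 2 else 1
        y_dot = np.gradient(y, dt, edge_order=edge)
        z_dot = np.gradient(z, dt, edge_order=edge)
        return cls(
            t=t,
            y=y,
            z=z,
            y_dot=y_dot,
            z_dot=z_dot,
            y_ddot=np.gradient(y_dot, dt, edge_order=edge),
            z_ddot=np.gradient(z_dot, dt, edge_order=edge),
        )

    @classmethod
    def stationary(cls, duration: float, sample_rate: float = DEFAULT_SAMPLE_RATE,
                   y0: float = 0.0, z0: float = 0.0) -> "PivotTrajectory":
        """A pivot that does not move for ``duration`` seconds."""
        n = int(round(duration * sample_rate)) + 1
        t = np.arange(n) / sample_rate
        zeros = np.zeros(n)
        return cls(t, np.full(n, y0), np.full(n, z0),
                   zeros, zeros, zeros, zeros)


class PendulumTrace:
    """Sequence of pendulum states over a block (array backed).

    Indexing yields :class:`PendulumState`; the raw ``t``, ``theta`` and
    ``theta_dot`` arrays are exposed for vectorised analysis.
    """

    def __init__(self, t, theta, theta_dot):
        self.t = np.asarray(t, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.theta_dot = np.asarray(theta_dot, dtype=float)
        if not (self.t.size == self.theta.size == self.theta_dot.size):
            raise ValueError("trace arrays must have equal length")
        self.dt = _uniform_dt(self.t)

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PendulumTrace(self.t[i], self.theta[i], self.theta_dot[i])
        return PendulumState(float(self.t[i]), float(self.theta[i]),
                             float(self.theta_dot[i]))

    @property
    def theta_wrapped(self) -> np.ndarray:
        return wrap_angle(self.theta)


def _accel(theta: float, theta_dot: float, y_ddot: float, z_ddot: float,
           params: PendulumParams) -> float:
    return (
        -(y_ddot * math.cos(theta) + (z_ddot + params.g) * math.sin(theta))
        / params.l
        - params.c / (params.m * params.l**2) * theta_dot
    )


def _rk4(theta: float, theta_dot: float, y_ddot: float, z_ddot: float,
         params: PendulumParams, dt: float) -> tuple[float, float]:
    k1v = _accel(theta, theta_dot, y_ddot, z_ddot, params)
    k1x = theta_dot
    k2v = _accel(theta + 0.5 * dt * k1x, theta_dot + 0.5 * dt * k1v,
                 y_ddot, z_ddot, params)
    k2x = theta_dot + 0.5 * dt * k1v
    k3v = _accel(theta + 0.5 * dt * k2x, theta_dot + 0.5 * dt * k2v,
                 y_ddot, z_ddot, params)
    k3x = theta_dot + 0.5 * dt * k2v
    k4v = _accel(theta + dt * k3x, theta_dot + dt * k3v, y_ddot, z_ddot, params)
    k4x = theta_dot + dt * k3v
    theta += dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    theta_dot += dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return theta, theta_dot


def step_dynamics(state: PendulumState, pivot_accel, params: PendulumParams,
                  dt: float) -> PendulumState:
    """Advance the pendulum by ``dt`` under a constant pivot acceleration.

    Classical fixed-step RK4; the pivot acceleration ``(y_ddot, z_ddot)`` is
    held constant over the step, as in a zero-order-hold real-time loop.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y_ddot, z_ddot = float(pivot_accel[0]), float(pivot_accel[1])
    vals = (state.theta, state.theta_dot, y_ddot, z_ddot, state.t)
    if not all(math.isfinite(v) for v in vals):
        raise InvalidStateError("non-finite state or pivot acceleration")
    theta, theta_dot = _rk4(state.theta, state.theta_dot, y_ddot, z_ddot,
                            params, dt)
    if not (math.isfinite(theta) and math.isfinite(theta_dot)):
        raise InvalidStateError("integration produced non-finite state")
    return PendulumState(state.t + dt, theta, theta_dot)


def simulate_block(pivot: PivotTrajectory, init: PendulumState,
                   params: PendulumParams,
                   max_step: float = 1.0 / DEFAULT_SAMPLE_RATE) -> PendulumTrace:
    """Simulate the pendulum over a whole block driven by a pivot trajectory.

    One pendulum state is returned per pivot sample.  The pivot acceleration
    is held constant over each sample interval; if the pivot sampling
    interval exceeds ``max_step`` the integrator sub-steps internally.
    """
    n = len(pivot)
    if n == 0:
        raise ValueError("empty pivot trajectory")
    if abs(init.t - pivot.t[0]) > 1e-9:
        raise ValueError("initial state time must match the trajectory start")
    dt = pivot.dt
    n_sub = max(1, int(math.ceil(dt / max_step - 1e-12)))
    h = dt / n_sub
    theta = np.empty(n)
    theta_dot = np.empty(n)
    th, thd = init.theta, init.theta_dot
    theta[0], theta_dot[0] = th, thd
    y_dd = pivot.y_ddot
    z_dd = pivot.z_ddot
    for i in range(n - 1):
        a_y, a_z = y_dd[i], z_dd[i]
        for _ in range(n_sub):
            th, thd = _rk4(th, thd, a_y, a_z, params, h)
        theta[i + 1] = th
        theta_dot[i + 1] = thd
    trace = PendulumTrace(pivot.t, theta, theta_dot)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(theta_dot))):
        raise InvalidStateError("simulation diverged to non-finite values")
    return trace


def rod_force(state, pivot_accel, params: PendulumParams):
    """Haptic force along the rod at the pivot (N), scalar or vectorised.

    ``F_rod = m*(theta_dot^2*l - y_dd*sin(theta) + (g + z_dd)*cos(theta))``;
    positive values push the pivot away from the ball along the rod.
    """
    if isinstance(state, (PendulumState,)):
        theta, theta_dot = state.theta, state.theta_dot
    else:
        theta, theta_dot = state
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    y_dd = np.asarray(pivot_accel[0], dtype=float)
    z_dd = np.asarray(pivot_accel[1], dtype=float)
    for arr in (theta, theta_dot, y_dd, z_dd):
        if not np.all(np.isfinite(arr)):
            raise InvalidStateError("non-finite input to rod_force")
    out = params.m * (
        theta_dot**2 * params.l
        - y_dd * np.sin(theta)
        + (params.g + z_dd) * np.cos(theta)
    )
    return float(out) if out.ndim == 0 else out


def decompose_rod_force(f_rod, theta):
    """Cartesian (F_y, F_z) components of the rod force at the pivot.

    Under the convention ball = pivot + l*(sin(theta), -cos(theta)), the rod
    force acts on the hand along the pivot-to-ball direction:
    ``F_y = F_rod*sin(theta)``, ``F_z = -F_rod*cos(theta)``; the magnitude is
    preserved.
    """
    f_rod = np.asarray(f_rod, dtype=float)
    theta = np.asarray(theta, dtype=float)
    f_y = f_rod * np.sin(theta)
    f_z = -f_rod * np.cos(theta)
    if f_y.ndim == 0:
        return float(f_y), float(f_z)
    return f_y, f_z


@dataclass(frozen=True)
class ScoreResult:
    """Accumulated score with the inversion intervals that produced it."""

    score: float
    inversion_intervals: tuple
    inverted_time: float


def inversion_mask(trace: PendulumTrace, params: PendulumParams) -> np.ndarray:
    """Boolean per-sample mask of the inversion condition."""
    dist = np.abs(wrap_angle(trace.theta - math.pi))
    return (dist < params.angle_tol) & (np.abs(trace.theta_dot) < params.speed_tol)


def compute_score(trace: PendulumTrace, params: PendulumParams) -> ScoreResult:
    """Accumulate the block score from a pendulum trace.

    The score integrates ``k*(angle_tol - |theta - pi|)`` (trapezoidal rule,
    wrapped angle distance) over every interval where the pendulum is inside
    the inversion window.  Within a block the score is retained across drops
    and resumes on re-inversion.  An interval starts at the first sample
    satisfying both conditions and ends at the first sample violating either.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    mask = inversion_mask(trace, params)
    dist = np.abs(wrap_angle(trace.theta - math.pi))
    rate = params.k * (params.angle_tol - dist)
    dt = trace.dt
    # contiguous runs of the mask
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]  # stop = first sample outside
    score = 0.0
    inverted = 0.0
    intervals = []
    for a, b in zip(starts, stops):
        seg = rate[a:b]
        if seg.size >= 2:
            score += float(np.trapezoid(seg, dx=dt))
        intervals.append((float(trace.t[a]), float(trace.t[min(b, len(trace) - 1)])))
        inverted += (b - a - 1) * dt if b - a >= 2 else 0.0
    return ScoreResult(score=score, inversion_intervals=tuple(intervals),
                       inverted_time=inverted)
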