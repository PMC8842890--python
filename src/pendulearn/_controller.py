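"""Compiled closed-loop block simulation for synthetic participants.

One numba kernel integrates, per sample, (a) a synthetic "participant"
controller that moves the pivot and (b) the pendulum it drives.  The
controller combines

* energy pumping toward the inverted state: horizontal pivot acceleration
  ``u = sat(k_e * (E - E_ref) * theta_dot*cos(theta))`` with ``E_ref``
  slightly above the upright energy, so the pendulum arrives at the top
  slowly enough to be caught;
* a near-inversion stabiliser ``u = -(g + l*kp)*phi - l*kd*theta_dot`` acting
  on the wrapped error ``phi = wrap(theta - pi)``, which linearises to a
  critically-dampable second-order loop about the inverted pose;
* a weak centering spring-damper on the pivot that keeps the workspace
  bounded (hard clip as backstop);
* sensorimotor imperfection: the controller reads the pendulum state with a
  delay (or a linear-extrapolation *lead* when the delay is negative) and its
  command is corrupted by white acceleration noise.

The pendulum step is the same zero-order-hold RK4 as
:func:`pendulearn.pendulum.step_dynamics`, so an open-loop replay of the
generated pivot trajectory through :func:`pendulearn.pendulum.simulate_block`
reproduces the pendulum states.
"""

import math

import numpy as np
from numba import njit

__all__ = ["simulate_block_kernel"]


@njit(cache=True)
def simulate_block_kernel(theta0, thetadot0, n, dt, m, l, g, cml2,
                          drive, k_e, kp, kd, capture_ang, capture_vel,
                          delay_steps, noise_y, noise_z,
                          y_spring, y_damp, z_spring, z_damp,
                          workspace, u_max):  # pragma: no cover - compiled
    theta = np.empty(n)
    thetadot = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    ydot = np.empty(n)
    zdot = np.empty(n)
    yddot = np.empty(n)
    zddot = np.empty(n)

    th = theta0
    thd = thetadot0
    yy = 0.0
    zz = 0.0
    vy = 0.0
    vz = 0.0
    e_top = 2.0 * m * g * l
    e_ref = 1.05 * e_top
    two_pi = 2.0 * math.pi

    for i in range(n):
        theta[i] = th
        thetadot[i] = thd
        y[i] = yy
        z[i] = zz
        ydot[i] = vy
        zdot[i] = vz
        if i == n - 1:
            yddot[i] = 0.0
            zddot[i] = 0.0
            break

        phi = (th - math.pi) % two_pi
        if phi > math.pi:
            phi -= two_pi

        if abs(phi) < capture_ang and abs(thd) < capture_vel:
            # balancing relies on a learned predictive internal model, so the
            # stabiliser acts on the current state
            u = -(g + l * kp) * phi - l * kd * thd
        else:
            # the pump's timing signal runs on the sensed (delayed, or
            # extrapolated ahead if leading) state; this sets the pivot-ball
            # phase relation and degrades pumping efficiency with delay.
            # The energy level itself is regulated on the current state
            # (amplitude perception is much slower than the swing cycle).
            if delay_steps > 0:
                j = i - delay_steps
                if j < 0:
                    j = 0
                th_d = theta[j]
                thd_d = thetadot[j]
            elif delay_steps < 0:
                th_d = th - delay_steps * dt * thd
                thd_d = thd
            else:
                th_d = th
                thd_d = thd
            e = 0.5 * m * l * l * thd * thd + m * g * l * (1.0 - math.cos(th))
            s = thd_d * math.cos(th_d)
            if e < 0.02 * e_top and abs(s) < 1e-6:
                u = -drive  # kick out of the dead hanging equilibrium
            else:
                u = k_e * (e - e_ref) * s
                if u > drive:
                    u = drive
                elif u < -drive:
                    u = -drive

        u += noise_y[i] - y_spring * yy - y_damp * vy
        if u > u_max:
            u = u_max
        elif u < -u_max:
            u = -u_max
        w = noise_z[i] - z_spring * zz - z_damp * vz
        if w > u_max:
            w = u_max
        elif w < -u_max:
            w = -u_max
        yddot[i] = u
        zddot[i] = w

        # pivot kinematics (constant accel over the step), clipped workspace
        yy = yy + vy * dt + 0.5 * u * dt * dt
        vy = vy + u * dt
        if yy > workspace:
            yy = workspace
            vy = 0.0
        elif yy < -workspace:
            yy = -workspace
            vy = 0.0
        zz = zz + vz * dt + 0.5 * w * dt * dt
        vz = vz + w * dt
        if zz > workspace:
            zz = workspace
            vz = 0.0
        elif zz < -workspace:
            zz = -workspace
            vz = 0.0

        # pendulum RK4 step, pivot acceleration held constant
        k1v = -(u * math.cos(th) + (w + g) * math.sin(th)) / l - cml2 * thd
        k1x = thd
        th2 = th + 0.5 * dt * k1x
        thd2 = thd + 0.5 * dt * k1v
        k2v = -(u * math.cos(th2) + (w + g) * math.sin(th2)) / l - cml2 * thd2
        k2x = thd2
        th3 = th + 0.5 * dt * k2x
        thd3 = thd + 0.5 * dt * k2v
        k3v = -(u * math.cos(th3) + (w + g) * math.sin(th3)) / l - cml2 * thd3
        k3x = thd3
        th4 = th + dt * k3x
        thd4 = thd + dt * k3v
        k4v = -(u * math.cos(th4) + (w + g) * math.sin(th4)) / l - cml2 * thd4
        k4x = thd4
        th = th + dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        thd = thd + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)

    return theta, thetadot, y, z, ydot, zdot, yddot, zddot
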