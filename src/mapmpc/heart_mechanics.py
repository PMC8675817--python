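"""Viscoelastic heart-muscle / transducer / injection-set mechanical model.

Muscle contraction, pressure transducer and infusion set are lumped into one
rotational mass-spring-damper: inertia ``J``, stiffness ``k`` (muscle
tension), viscosity ``B`` (line and tissue resistance).  An external torque
``Mx(t)`` (the pressure surge) works against the internally generated torque,
whose resting component is ``M0(t)``; the internal torque is transmitted
through the spring, M = k (theta - theta1), and the damper end obeys
M = M0 + B d(theta1)/dt.  Eliminating theta1 gives the third-order kinetics

    (B J / k) theta''' + J theta'' + B theta' = Mx(t) - M0(t),

i.e. the torque difference DeltaM = Mx - M0 drives the angular excursion
theta through the transfer function 1 / ( s ((BJ/k) s^2 + J s + B) ).  A
constant torque difference A therefore settles the angular rate at A/B (the
final-value theorem on the velocity transfer function), while theta itself
ramps: the pure integrator reflects that a sustained pressure excess keeps
the muscle moving.

The module is a standalone mechanical model; it is not inserted into the
blood-pressure control loop (no coupling law is defined for that), but the
loop's infusion signal can be fed in as Mx for illustration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.integrate import odeint, solve_ivp

__all__ = [
    "MuscleModel",
    "MuscleResponse",
    "muscle_transfer_function",
    "simulate_muscle",
    "velocity_transfer_function",
]


@dataclass(frozen=True)
class MuscleModel:
    """J: inertia (torque s^2/rad), B: viscosity (torque s/rad), k: stiffness (torque/rad)."""

    J: float = 1.0
    B: float = 1.0
    k: float = 1.0

    def __post_init__(self):
        for name in ("J", "B", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"muscle parameter {name} must be positive")


def muscle_transfer_function(model: MuscleModel) -> signal.TransferFunction:
    """theta(s) / DeltaM(s) = 1 / ( s ((BJ/k) s^2 + J s + B) )."""
    return signal.TransferFunction(
        [1.0], [model.B * model.J / model.k, model.J, model.B, 0.0]
    )


def velocity_transfer_function(model: MuscleModel) -> signal.TransferFunction:
    """theta_dot(s) / DeltaM(s); its DC gain is 1/B."""
    return signal.TransferFunction(
        [1.0], [model.B * model.J / model.k, model.J, model.B]
    )


@dataclass
class MuscleResponse:
    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    torque: np.ndarray  # internally transmitted torque M(t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "theta": self.theta,
                "theta_dot": self.theta_dot,
                "torque": self.torque,
            }
        )


def simulate_muscle(
    model: MuscleModel, Mx, M0, Ts: float, n: int | None = None
) -> MuscleResponse:
    """Integrate the muscle kinetics from rest under sampled torque inputs.

    ``Mx`` and ``M0`` are sequences sampled at ``Ts`` and held constant
    between samples (zero-order hold).  Integration is adaptive Runge-Kutta
    restarted at every sample instant so the input discontinuities never fall
    inside an integrator step.  Returns theta, theta_dot and the transmitted
    torque M = Mx - J theta_dotdot at the sample instants.
    """
    if Ts <= 0:
        raise ValueError("sampling time must be positive")
    Mx = np.asarray(Mx, dtype=float)
    M0 = np.asarray(M0, dtype=float)
    if n is None:
        n = min(len(Mx), len(M0))
    if len(Mx) < n or len(M0) < n:
        raise ValueError("torque sequences shorter than the requested window")
    dm = Mx[:n] - M0[:n]
    c3 = model.B * model.J / model.k

    theta = np.zeros(n + 1)
    theta_dot = np.zeros(n + 1)
    theta_ddot = np.zeros(n + 1)
    x = np.zeros(3)  # (theta, theta_dot, theta_ddot)
    span = np.array([0.0, Ts])
    J, B = model.J, model.B

    def rhs(x, _t, u):
        return (x[1], x[2], (u - J * x[2] - B * x[1]) / c3)

    def jac(_x, _t, _u):
        return ((0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.0, -B / c3, -J / c3))

    # near the rigid-spring limit (k large) the fast mode k/B makes the
    # equation stiff; take the L-stable implicit solver from the start then
    stiff = (model.k / model.B) * Ts > 1e3

    for i in range(n):
        # restart at every sample so the held-input discontinuities never fall
        # inside an integrator step
        if not stiff:
            out, info = odeint(
                rhs, x, span, args=(dm[i],), Dfun=jac,
                rtol=1e-10, atol=1e-12, mxstep=10000, full_output=True,
                tfirst=False,
            )
            ok = info["message"] == "Integration successful."
            if ok:
                x = out[-1]
        if stiff or not ok:
            sol = solve_ivp(
                lambda t, y, u=dm[i]: rhs(y, t, u),
                (0.0, Ts), x, method="Radau",
                jac=lambda t, y, u=dm[i]: np.asarray(jac(y, t, u)),
                rtol=1e-10, atol=1e-12,
            )
            if not sol.success:
                raise RuntimeError(
                    f"muscle integration failed on sample {i}: {sol.message}; "
                    "try a smaller sampling time"
                )
            x = sol.y[:, -1]
        theta[i + 1], theta_dot[i + 1], theta_ddot[i + 1] = x
    t = np.arange(n) * Ts
    # internal torque from the torque balance Mx - M = J theta_ddot
    torque = Mx[:n] - model.J * theta_ddot[:n]
    return MuscleResponse(
        t=t, theta=theta[:n], theta_dot=theta_dot[:n], torque=torque
    )
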