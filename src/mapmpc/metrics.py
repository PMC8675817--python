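"""Control-performance indices over a closed-loop run.

Standardized discrete-sum definitions over a window of N samples with
sampling time Ts:

    IAE = sum |e(k)| Ts        ISE = sum e(k)^2 Ts        MSE = (1/N) sum e(k)^2

so that ISE = MSE * N * Ts always holds.

Two error conventions are supported.  The raw error is e(k) = r(k) - y(k).
With ``delay_align = d`` the reference is shifted by the plant's transport
delay, e(k) = r(k-d) - y(k): during the first d samples no causal controller
can move the output at all, so the aligned error measures only the part of
the error the controller is accountable for.  The experiment tables report
the aligned indices; both variants are available.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import signal

__all__ = ["MetricsReport", "actuator_limited_bounds", "compute_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    IAE: float
    ISE: float
    MSE: float
    n: int
    Ts: float

    def to_dict(self) -> dict:
        return asdict(self)


def _aligned_reference(r: np.ndarray, delay_align: int, fill: float) -> np.ndarray:
    if delay_align == 0:
        return r
    out = np.empty_like(r)
    out[:delay_align] = fill
    out[delay_align:] = r[: len(r) - delay_align]
    return out


def compute_metrics(
    history,
    window: slice | None = None,
    delay_align: int = 0,
    align_fill: float = 0.0,
) -> MetricsReport:
    """IAE/ISE/MSE of a :class:`~mapmpc.mpc_controller.ClosedLoopHistory`.

    ``window`` restricts the evaluation to a slice of the run; ``delay_align``
    shifts the reference by that many samples (pre-window reference samples
    take the value ``align_fill``, the pre-run set-point).
    """
    r = np.asarray(history.r, dtype=float)
    y = np.asarray(history.y, dtype=float)
    Ts = float(history.Ts)
    if delay_align < 0:
        raise ValueError("delay_align must be nonnegative")
    e = _aligned_reference(r, delay_align, align_fill) - y
    if window is not None:
        e = e[window]
    n = len(e)
    if n == 0:
        raise ValueError("empty evaluation window")
    iae = float(np.sum(np.abs(e)) * Ts)
    ise = float(np.sum(e**2) * Ts)
    return MetricsReport(IAE=iae, ISE=ise, MSE=ise / (n * Ts), n=n, Ts=Ts)


def actuator_limited_bounds(
    model, u_max: float = 2.0, amplitude: float = 1.0, t_max: float = 400.0
) -> dict:
    """Lower bounds on IAE/ISE imposed by the input limit alone.

    No controller can shrink the step-tracking error faster than the plant
    driven flat-out: with the input pinned at ``u_max`` the output follows
    ``u_max * s(t)`` (s = delay-free unit step response), so until the first
    crossing of the set-point the error is at least ``amplitude - u_max s(t)``
    -- even with perfect dead-time compensation and the dead-time interval
    excluded from the window.  Returns the crossing time and the integrals of
    that floor, the saturation-limited IAE/ISE bounds.
    """
    t = np.arange(0.0, t_max, 0.05)
    _, s = signal.step((list(model.num), list(model.den)), T=t)
    y = u_max * s
    above = np.nonzero(y >= amplitude)[0]
    if len(above) == 0:
        raise ValueError(
            f"set-point {amplitude} unreachable with u_max={u_max} within "
            f"{t_max} s (plant DC gain {model.dc_gain:g})"
        )
    i = above[0]
    e = np.clip(amplitude - y[:i], 0.0, None)
    return {
        "t_reach_s": float(t[i]),
        "IAE_lower_bound": float(np.trapezoid(e, t[:i])),
        "ISE_lower_bound": float(np.trapezoid(e**2, t[:i])),
    }
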