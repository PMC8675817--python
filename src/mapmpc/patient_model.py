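"""Dead-time patient model of mean arterial pressure response to sodium nitroprusside.

The pressure change :math:`\\Delta MAP` produced by an SNP infusion rate is
modelled as a third-order rational transfer function with a transport delay,

.. math::

    \\frac{\\Delta MAP(s)}{SNP(s)} =
    \\frac{K (1 + T_3 s)\\, e^{-\\theta s}}
         {\\big((1 + T_3 s)(1 + T_2 s) - \\alpha\\big)(1 + T_1 s)},

where ``K`` is the patient's drug sensitivity (mmHg per ml/h), ``T1..T3`` are
drug-effect time constants, ``alpha`` the drug recirculation fraction and
``theta`` the transport delay.  The canonical patient instance used throughout
the package is stored directly in expanded polynomial form

.. math::

    G_p(s) = \\frac{5 (1 + 30 s)\\, e^{-60 s}}{1 + 130 s + 4600 s^2 + 30000 s^3},

because the individual ``(K, T1, T2, T3, alpha)`` decomposition that generates
it is not uniquely determined and is deliberately not reverse-engineered.

Discretization is exact zero-order-hold (matrix exponential, via
:func:`scipy.signal.cont2discrete`); the transport delay becomes an integer
number of samples.  The resulting difference equation for the canonical model
at ``Ts = 1`` s is

    y(k) = -a2 y(k-1) - a1 y(k-2) - a0 y(k-3)
           + b2 u(k-61) + b1 u(k-62) + b0 u(k-63).

Outputs are normalized: a settled value of 1 means "pressure moved the full
way from the initial to the target MAP".  :class:`DisplayMapping` renders the
normalized output in absolute mmHg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "ContinuousPatientModel",
    "DiscretePatientModel",
    "DisplayMapping",
    "InitialHistory",
    "PlantSimulator",
    "build_continuous_model",
    "canonical_model",
    "continuous_from_config",
    "discretize_zoh",
    "simulate",
    "step_response",
]


@dataclass(frozen=True)
class DisplayMapping:
    """Affine map from the normalized model output to absolute MAP in mmHg.

    ``map_initial`` is the patient's pressure before the infusion starts,
    ``map_target`` the set-point; a normalized output of 1 therefore reads
    as the target pressure.
    """

    map_initial: float = 40.0
    map_target: float = 80.0

    @property
    def span(self) -> float:
        return self.map_target - self.map_initial

    def to_mmhg(self, y) -> np.ndarray:
        return self.map_initial + self.span * np.asarray(y, dtype=float)

    def normalize_amplitude(self, amplitude_mmhg: float) -> float:
        """Convert an amplitude given in mmHg to normalized output units."""
        return float(amplitude_mmhg) / self.span


@dataclass(frozen=True)
class ContinuousPatientModel:
    """Delay + rational transfer function, polynomials in descending powers of s.

    Invariants: the denominator constant term is 1 (enforced by normalization
    at construction), the dead time is nonnegative.
    """

    num: tuple
    den: tuple
    dead_time: float = 0.0

    def __post_init__(self):
        num = np.atleast_1d(np.asarray(self.num, dtype=float))
        den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if den[-1] <= 0:
            raise ValueError(
                "denominator constant term must be positive (got %g); "
                "the model normalizes it to 1" % den[-1]
            )
        if self.dead_time < 0:
            raise ValueError("dead time must be nonnegative")
        scale = den[-1]
        object.__setattr__(self, "num", tuple(num / scale))
        object.__setattr__(self, "den", tuple(den / scale))
        object.__setattr__(self, "dead_time", float(self.dead_time))

    @property
    def dc_gain(self) -> float:
        """Steady-state gain, the transfer function evaluated at s = 0."""
        return self.num[-1] / self.den[-1]

    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    @property
    def is_stable(self) -> bool:
        return bool(np.all(self.poles().real < 0))

    def delay_free_tf(self) -> signal.TransferFunction:
        """The rational part as a scipy TransferFunction (delay excluded)."""
        return signal.TransferFunction(list(self.num), list(self.den))

    def frequency_response(self, w: np.ndarray) -> np.ndarray:
        """Complex response at angular frequencies ``w`` including the delay."""
        w = np.asarray(w, dtype=float)
        _, h = signal.freqs(self.num, self.den, worN=w)
        return h * np.exp(-1j * w * self.dead_time)


def build_continuous_model(
    K: float, T1: float, T2: float, T3: float, alpha: float, theta: float
) -> ContinuousPatientModel:
    """Assemble the parametric MAP/SNP model from its physiological constants.

    Parameters
    ----------
    K : drug sensitivity, mmHg per ml/h.
    T1, T2, T3 : drug-effect time constants, seconds (all > 0).
    alpha : recirculation fraction, dimensionless, 0 <= alpha < 1.
    theta : transport delay, seconds (>= 0).
    """
    for name, T in (("T1", T1), ("T2", T2), ("T3", T3)):
        if T <= 0:
            raise ValueError(f"time constant {name} must be positive, got {T}")
    if not (0 <= alpha < 1):
        raise ValueError(
            f"recirculation fraction alpha must satisfy 0 <= alpha < 1, got {alpha}"
        )
    if theta < 0:
        raise ValueError(f"dead time must be nonnegative, got {theta}")
    # ((1 + T3 s)(1 + T2 s) - alpha)(1 + T1 s), expanded by convolution
    inner = np.polymul([T3, 1.0], [T2, 1.0])
    inner[-1] -= alpha
    den = np.polymul(inner, [T1, 1.0])
    num = np.array([K * T3, K], dtype=float)
    return ContinuousPatientModel(num=tuple(num), den=tuple(den), dead_time=theta)


def canonical_model() -> ContinuousPatientModel:
    """The canonical patient: 5(1+30s)e^{-60s} / (1 + 130s + 4600s^2 + 30000s^3)."""
    return ContinuousPatientModel(
        num=(150.0, 5.0), den=(30000.0, 4600.0, 130.0, 1.0), dead_time=60.0
    )


def continuous_from_config(cfg: dict) -> ContinuousPatientModel:
    """Build a model from a configuration mapping.

    Recognized keys: ``gain``, ``time_constants`` (list [T1, T2, T3]),
    ``alpha``, ``dead_time_s``.  An empty/missing parameter set yields the
    canonical patient.
    """
    if not cfg or "gain" not in cfg:
        return canonical_model()
    T1, T2, T3 = cfg["time_constants"]
    return build_continuous_model(
        K=cfg["gain"],
        T1=T1,
        T2=T2,
        T3=T3,
        alpha=cfg.get("alpha", 0.0),
        theta=cfg.get("dead_time_s", 0.0),
    )


@dataclass(frozen=True)
class DiscretePatientModel:
    """ZOH-equivalent discrete model: delay-free rational part + integer delay.

    ``num``/``den`` are in descending powers of z with a monic denominator;
    for the canonical third-order case ``num = (b2, b1, b0)`` and
    ``den = (1, a2, a1, a0)``.  ``delay`` is the dead time in samples.
    """

    num: tuple
    den: tuple
    delay: int
    Ts: float

    def __post_init__(self):
        num = np.atleast_1d(np.asarray(self.num, dtype=float))
        den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if abs(den[0]) < 1e-300:
            raise ValueError("denominator leading coefficient must be nonzero")
        num = num / den[0]
        den = den / den[0]
        if len(num) > len(den):
            raise ValueError("numerator order exceeds denominator order")
        if self.delay < 0:
            raise ValueError("sample delay must be nonnegative")
        if self.Ts <= 0:
            raise ValueError("sampling time must be positive")
        object.__setattr__(self, "num", tuple(num))
        object.__setattr__(self, "den", tuple(den))
        object.__setattr__(self, "delay", int(self.delay))
        object.__setattr__(self, "Ts", float(self.Ts))

    # Named coefficients in the difference-equation convention
    # y(k) = -a2 y(k-1) - a1 y(k-2) - a0 y(k-3) + b2 u(k-d-1) + ...
    @property
    def a_coeffs(self) -> tuple:
        """(a0, a1, ..., a_{n-1}): ascending-power denominator coefficients."""
        return tuple(self.den[1:][::-1])

    @property
    def b_coeffs(self) -> tuple:
        """(b0, b1, ..., bm): ascending-power numerator coefficients."""
        return tuple(self.num[::-1])

    @property
    def order(self) -> int:
        return len(self.den) - 1

    @property
    def dc_gain(self) -> float:
        return float(np.sum(self.num) / np.sum(self.den))

    def poles(self) -> np.ndarray:
        return np.roots(self.den) if self.order > 0 else np.array([])

    @property
    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.poles()) < 1.0))


def discretize_zoh(model: ContinuousPatientModel, Ts: float) -> DiscretePatientModel:
    """Exact zero-order-hold discretization; the delay becomes ``round(theta/Ts)``.

    If the dead time is not an integer multiple of ``Ts`` it is rounded to the
    nearest sample with a warning (the fractional part is dropped, not
    Thiran-approximated).
    """
    if Ts <= 0:
        raise ValueError("sampling time must be positive")
    d_exact = model.dead_time / Ts
    d = int(round(d_exact))
    if abs(d_exact - d) > 1e-9:
        warnings.warn(
            f"dead time {model.dead_time} s is not an integer multiple of "
            f"Ts={Ts} s; rounding the sample delay to {d}",
            stacklevel=2,
        )
    num = np.atleast_1d(np.asarray(model.num, dtype=float))
    den = np.atleast_1d(np.asarray(model.den, dtype=float))
    if len(den) == 1:
        # static gain: no dynamics to hold
        return DiscretePatientModel(
            num=(num[-1] / den[0],), den=(1.0,), delay=d, Ts=Ts
        )
    try:
        numd, dend, _ = signal.cont2discrete((num, den), dt=Ts, method="zoh")
    except Exception as exc:  # pragma: no cover - scipy surfaces its own detail
        raise ArithmeticError(
            f"zero-order-hold discretization failed for den={den}: {exc}"
        ) from exc
    numd = np.atleast_1d(np.squeeze(numd))
    # strip the structural leading zero of a strictly proper system
    nz = np.nonzero(np.abs(numd) > 1e-300)[0]
    numd = numd[nz[0] :] if len(nz) else np.array([0.0])
    if not np.all(np.isfinite(numd)) or not np.all(np.isfinite(dend)):
        raise ArithmeticError(
            "zero-order-hold discretization produced non-finite coefficients; "
            "the matrix exponential is ill-conditioned for these parameters"
        )
    return DiscretePatientModel(num=tuple(numd), den=tuple(dend), delay=d, Ts=Ts)


@dataclass
class InitialHistory:
    """Past samples, newest first: ``past_y[0] = y(-1)``, ``past_u[0] = u(-1)``."""

    past_y: np.ndarray
    past_u: np.ndarray

    @classmethod
    def zeros(cls, dmodel: DiscretePatientModel) -> "InitialHistory":
        n = dmodel.order
        m = len(dmodel.num) - 1
        return cls(
            past_y=np.zeros(n), past_u=np.zeros(dmodel.delay + (n - m) + m)
        )


def simulate(
    dmodel: DiscretePatientModel,
    u,
    disturbance=None,
    history: InitialHistory | None = None,
) -> np.ndarray:
    """Run the difference equation over ``len(u)`` steps and return the measured output.

    The plant recursion is

        y(k) = -sum_i a_i' y(k-i) + sum_j b_j' u(k - d - (n-m) - j)

    (primes denote descending-power coefficients), i.e. for the canonical model
    ``y(k) = -a2 y(k-1) - a1 y(k-2) - a0 y(k-3) + b2 u(k-61) + b1 u(k-62) + b0 u(k-63)``.
    ``disturbance`` is added to the model output sample-by-sample (output-additive
    measurement-side disturbance).  Past samples default to rest (all zeros).
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("input sequence must be one-dimensional")
    N = len(u)
    if disturbance is not None:
        disturbance = np.asarray(disturbance, dtype=float)
        if len(disturbance) < N:
            raise ValueError(
                f"disturbance length {len(disturbance)} shorter than input length {N}"
            )
    if history is None:
        history = InitialHistory.zeros(dmodel)
    n = dmodel.order
    m = len(dmodel.num) - 1
    off = dmodel.delay + (n - m)  # input age of the leading numerator tap
    py = np.asarray(history.past_y, dtype=float)[::-1]  # oldest first
    pu = np.asarray(history.past_u, dtype=float)[::-1]
    if len(py) < n or len(pu) < off + m:
        raise ValueError(
            f"initial history too short: need >= {n} past outputs and "
            f">= {off + m} past inputs, got {len(py)} and {len(pu)}"
        )
    Y = np.concatenate([py, np.zeros(N)])
    U = np.concatenate([pu, u])
    Ly, Lu = len(py), len(pu)
    a = np.asarray(dmodel.den[1:], dtype=float)  # descending: multiplies y(k-1..k-n)
    b = np.asarray(dmodel.num, dtype=float)  # descending: multiplies u(k-off-j)
    for k in range(N):
        ky = Ly + k
        ku = Lu + k
        acc = 0.0
        for i in range(1, n + 1):
            acc -= a[i - 1] * Y[ky - i]
        for j in range(m + 1):
            acc += b[j] * U[ku - off - j]
        Y[ky] = acc
    y = Y[Ly:]
    if disturbance is not None:
        y = y + disturbance[:N]
    return y


def step_response(dmodel: DiscretePatientModel, n_samples: int) -> np.ndarray:
    """Unit-step response from rest; the first ``delay`` samples are exactly zero."""
    if n_samples <= dmodel.delay:
        raise ValueError(
            f"n_samples={n_samples} must exceed the sample delay {dmodel.delay}"
        )
    return simulate(dmodel, np.ones(n_samples))


class PlantSimulator:
    """Stateful one-step-at-a-time wrapper around the difference equation.

    The output at the current step depends only on strictly earlier inputs
    (the ZOH model is strictly proper), so a closed loop may read
    :meth:`output` before choosing the input it then feeds to :meth:`advance`.
    """

    def __init__(
        self, dmodel: DiscretePatientModel, history: InitialHistory | None = None
    ):
        self.dmodel = dmodel
        h = history if history is not None else InitialHistory.zeros(dmodel)
        n = dmodel.order
        m = len(dmodel.num) - 1
        self._off = dmodel.delay + (n - m)
        if self._off == 0:
            raise ValueError(
                "direct-feedthrough model (no delay, equal orders): the "
                "step-wise simulator needs a strictly causal plant; use simulate()"
            )
        self._n, self._m = n, m
        need_u = self._off + m
        py = np.asarray(h.past_y, dtype=float)
        pu = np.asarray(h.past_u, dtype=float)
        if len(py) < n or len(pu) < need_u:
            raise ValueError("initial history too short for this model")
        self._py = list(py[:n])  # newest first
        self._pu = list(pu[:need_u])
        self._cached_output: float | None = None

    def output(self) -> float:
        """Model output at the current step (before the current input is applied)."""
        if self._cached_output is None:
            a = self.dmodel.den[1:]
            b = self.dmodel.num
            acc = 0.0
            for i in range(self._n):
                acc -= a[i] * self._py[i]
            for j in range(self._m + 1):
                acc += b[j] * self._pu[self._off - 1 + j]
            self._cached_output = acc
        return self._cached_output

    def advance(self, u_now: float) -> float:
        """Apply the current input, push the step into history, return the output."""
        y = self.output()
        self._py = [y] + self._py[:-1]
        if self._pu:
            self._pu = [float(u_now)] + self._pu[:-1]
        self._cached_output = None
        return y

    def history(self) -> InitialHistory:
        """Snapshot of the buffers, suitable for :func:`simulate` look-ahead."""
        return InitialHistory(
            past_y=np.array(self._py), past_u=np.array(self._pu)
        )
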