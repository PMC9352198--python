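"""Dopamine/GABA circuit with exact adaptation and fold-change detection.

The model describes the mean firing rate of a dopaminergic population ``d``
that is driven by the logarithm of the expected-reward input ``R(t)`` and
inhibited by a GABAergic population ``g``:

    d' = omega_d * (C + mu*log R - alpha*g - d)
    g' = omega   * (d/d0 - 1)

The integral feedback through ``g`` makes ``d`` adapt exactly to its baseline
``d0`` under any constant input, and because the input enters only through
``log R`` the full output dynamics depend on fold changes of ``R`` alone
(fold-change detection, FCD).  Besides this default ``feedback`` wiring the
module provides a ``feedforward`` FCD variant (expected reward drives ``g``
directly), a ``quasi_static`` variant that eliminates the fast ``d`` equation
algebraically, and a ``rectified`` variant that keeps ``d`` non-negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "CircuitParams",
    "CircuitState",
    "CircuitTrace",
    "MOUSE",
    "PRIMATE",
    "steady_state",
    "simulate",
    "quasi_static_output",
    "response_amplitude",
    "reward_response_after_adaptation",
    "make_propagator",
]

_VARIANTS = ("feedback", "feedforward", "quasi_static", "rectified")


@dataclass(frozen=True)
class CircuitParams:
    """Circuit constants.

    Parameters
    ----------
    omega_d : float
        Dopamine relaxation rate, 1/s.
    omega : float
        Adaptation rate of the GABAergic integrator, 1/s.
    C : float
        Baseline dopaminergic drive at ``log R = g = 0``, spikes/s.
    mu : float
        Gain of the logarithmic reward activation, spikes/s.
    alpha : float
        GABAergic inhibition strength, dimensionless.
    d0 : float
        Adapted (homeostatic) dopamine level, spikes/s.
    variant : str
        One of ``feedback``, ``feedforward``, ``quasi_static``, ``rectified``.
    k_d : float
        Rectification constant of the rectified variant, spikes/s.
    """

    omega_d: float = 50.0
    omega: float = 15.0
    C: float = 15.0
    mu: float = 6.0
    alpha: float = 0.7
    d0: float = 5.0
    variant: str = "feedback"
    k_d: float = 1.0

    def __post_init__(self) -> None:
        if self.omega_d <= 0 or self.omega <= 0:
            raise ValueError("omega_d and omega must be positive rates")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.k_d < 0:
            raise ValueError("k_d must be non-negative")
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {_VARIANTS}")
        if self.omega_d < 2.0 * self.omega:
            warnings.warn(
                "omega_d is not large compared with omega; the intended "
                "fast-dopamine regime assumes omega_d >> omega",
                stacklevel=2,
            )

    def with_variant(self, variant: str, **kwargs) -> "CircuitParams":
        return replace(self, variant=variant, **kwargs)


#: Parameter presets estimated from mouse and primate recordings.
MOUSE = CircuitParams(omega_d=50.0, omega=15.0, C=15.0, mu=6.0, alpha=0.7, d0=5.0)
PRIMATE = CircuitParams(omega_d=100.0, omega=30.0, C=15.0, mu=6.0, alpha=0.7, d0=5.0)

PRESETS = {"mouse": MOUSE, "primate": PRIMATE}


@dataclass(frozen=True)
class CircuitState:
    """Instantaneous circuit state: dopamine ``d``, GABA ``g`` (spikes/s), time ``t`` (s)."""

    d: float
    g: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d) and math.isfinite(self.g) and math.isfinite(self.t)):
            raise ValueError("circuit state must be finite")


@dataclass
class CircuitTrace:
    """Time series of the simulated circuit.

    ``times`` is a strictly increasing grid (s); ``d_series``, ``g_series``
    and ``logR_series`` are aligned arrays.  ``d0`` records the adapted
    baseline so downstream analytics can measure deviations from it.
    """

    times: np.ndarray
    d_series: np.ndarray
    g_series: np.ndarray
    logR_series: np.ndarray
    d0: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d_series = np.asarray(self.d_series, dtype=float)
        self.g_series = np.asarray(self.g_series, dtype=float)
        self.logR_series = np.asarray(self.logR_series, dtype=float)
        n = self.times.size
        if not (self.d_series.size == self.g_series.size == self.logR_series.size == n):
            raise ValueError("trace series must have equal lengths")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "R": np.exp(self.logR_series),
                "logR": self.logR_series,
                "d": self.d_series,
                "g": self.g_series,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _check_positive_reward(R0: float) -> float:
    R0 = float(R0)
    if not (R0 > 0 and math.isfinite(R0)):
        raise ValueError(f"expected reward must be positive and finite, got {R0}")
    return R0


def steady_state(params: CircuitParams, R0: float) -> CircuitState:
    """Fixed point of the circuit under the constant input ``R0``.

    All variants adapt exactly: ``d = d0``.  The GABAergic level tracks the
    logarithm of the input; for the feedback wiring
    ``g = (C - d0 + mu*log R0)/alpha``, for the feed-forward wiring
    ``g = (C + mu*log R0)/alpha``, and the rectified variant's non-negative
    fixed point sits at ``g = (C - d0 - k_d + mu*log R0)/alpha``.
    """
    R0 = _check_positive_reward(R0)
    logR = math.log(R0)
    p = params
    if p.variant == "feedforward":
        g = (p.C + p.mu * logR) / p.alpha
    elif p.variant == "rectified":
        g = (p.C - p.d0 - p.k_d + p.mu * logR) / p.alpha
    else:  # feedback, quasi_static
        g = (p.C - p.d0 + p.mu * logR) / p.alpha
    return CircuitState(d=p.d0, g=g, t=0.0)


def quasi_static_output(params: CircuitParams, R: float, g: float) -> float:
    """Dopamine output with the fast equation eliminated: ``C + mu*log R - alpha*g``.

    The rectified variant returns ``max(0, C + mu*log R - alpha*g - k_d)``,
    the non-negative branch of the implicit relation
    ``d = (C + mu*log R - alpha*g) * d/(d + k_d)``.
    """
    R = _check_positive_reward(R)
    f = params.C + params.mu * math.log(R) - params.alpha * g
    if params.variant == "rectified":
        return max(0.0, f - params.k_d)
    return f


def _rhs(params: CircuitParams, log_R):
    """Right-hand side of the ODE system for the chosen variant.

    ``log_R`` maps time to log expected reward.  feedback/feedforward evolve
    (d, g); quasi_static and rectified evolve g alone with d algebraic.
    """
    p = params
    if p.variant == "feedback":

        def f(t, y):
            d, g = y
            return (
                p.omega_d * (p.C + p.mu * log_R(t) - p.alpha * g - d),
                p.omega * (d / p.d0 - 1.0),
            )

        return f, 2
    if p.variant == "feedforward":

        def f(t, y):
            d, g = y
            lr = log_R(t)
            return (
                p.omega_d * (p.d0 + p.C + p.mu * lr - p.alpha * g - d),
                p.omega * ((p.C + p.mu * lr) / p.alpha - g),
            )

        return f, 2
    if p.variant == "quasi_static":

        def f(t, y):
            d = p.C + p.mu * log_R(t) - p.alpha * y[0]
            return (p.omega * (d / p.d0 - 1.0),)

        return f, 1
    # rectified
    def f(t, y):
        d = max(0.0, p.C + p.mu * log_R(t) - p.alpha * y[0] - p.k_d)
        return (p.omega * (d / p.d0 - 1.0),)

    return f, 1


def _algebraic_d(params: CircuitParams, logR: np.ndarray, g: np.ndarray) -> np.ndarray:
    f = params.C + params.mu * logR - params.alpha * g
    if params.variant == "rectified":
        return np.maximum(0.0, f - params.k_d)
    return f


def simulate(
    params: CircuitParams,
    R,
    t_grid,
    init: CircuitState | str = "adapted",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> CircuitTrace:
    """Integrate the circuit under the reward signal ``R`` on ``t_grid``.

    ``R`` is a :class:`~rewardtaxis.fields.RewardSignal` (or any callable with
    an optional ``discontinuities`` attribute).  Integration restarts at each
    listed discontinuity so step inputs are treated as exact jumps rather
    than smoothed.  ``init="adapted"`` starts from the steady state at
    ``R(t_grid[0])``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D grid with at least two points")
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")

    R_vals = np.asarray(R(t_grid), dtype=float)
    if np.any(~np.isfinite(R_vals)) or np.any(R_vals <= 0):
        raise ValueError("reward signal must be positive and finite on the grid")
    logR_vals = np.log(R_vals)

    def log_R(t):
        return math.log(float(R(t)))

    if init == "adapted":
        st = steady_state(params, float(R(t_grid[0])))
    elif isinstance(init, CircuitState):
        st = init
    else:
        raise ValueError("init must be a CircuitState or 'adapted'")

    rhs, dim = _rhs(params, log_R)
    y = [st.d, st.g] if dim == 2 else [st.g]

    discs = sorted(set(getattr(R, "discontinuities", ())))
    t0, t1 = t_grid[0], t_grid[-1]
    breaks = [t for t in discs if t0 < t < t1]
    segments = np.concatenate([[t0], breaks, [t1]])

    d_out = np.empty_like(t_grid)
    g_out = np.empty_like(t_grid)
    eps = 1e-12
    for a, b in zip(segments[:-1], segments[1:]):
        # evaluate the signal strictly inside the segment so the jump at the
        # left edge is seen immediately
        mid_shift = eps * max(1.0, abs(a))

        def log_R_seg(t, _a=a, _s=mid_shift):
            return math.log(float(R(max(t, _a + _s))))

        rhs_seg, _ = _rhs(params, log_R_seg)
        mask = (t_grid >= a) & (t_grid <= b)
        ts = t_grid[mask]
        sol = solve_ivp(
            rhs_seg,
            (a, b),
            y,
            method="RK45",
            t_eval=ts if ts.size else None,
            rtol=rtol,
            atol=atol,
            max_step=(b - a),
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
        if ts.size:
            if dim == 2:
                d_out[mask] = sol.y[0]
                g_out[mask] = sol.y[1]
            else:
                g_out[mask] = sol.y[0]
        y = [float(v[-1]) for v in sol.y]

    if dim == 1:
        d_out = _algebraic_d(params, logR_vals, g_out)
    else:
        # at exact discontinuity times report the post-jump algebraic input
        pass
    return CircuitTrace(t_grid, d_out, g_out, logR_vals, d0=params.d0)


def response_amplitude(trace: CircuitTrace, window: tuple[float, float]) -> float:
    """Signed peak deviation of ``d`` from baseline within ``window = (t_a, t_b)``."""
    t_a, t_b = window
    if t_b < t_a:
        raise ValueError("window must satisfy t_a <= t_b")
    mask = (trace.times >= t_a) & (trace.times <= t_b)
    if not np.any(mask):
        raise ValueError("window contains no trace samples")
    dev = trace.d_series[mask] - trace.d0
    return float(dev[np.argmax(np.abs(dev))])


def reward_response_after_adaptation(
    params: CircuitParams, V_s: float, r: float, V_sprime: float
) -> float:
    """Adapted-state phasic response to a state transition.

    After adapting to an expected reward ``V(s)``, a transition delivering
    reward ``r`` into a state of value ``V(s')`` produces
    ``delta_d = mu * (log(r + V(s')) - log V(s))`` — the circuit reads out a
    logarithmic prediction error.
    """
    if not V_s > 0:
        raise ValueError("V_s must be positive")
    if not (r + V_sprime) > 0:
        raise ValueError("r + V_sprime must be positive")
    return params.mu * (math.log(r + V_sprime) - math.log(V_s))


def make_propagator(params: CircuitParams, dt: float):
    """Exact one-step propagator of the circuit for input held constant over ``dt``.

    For the feedback and feed-forward variants the system is linear in
    ``(d, g)`` once ``log R`` is frozen, so the update
    ``u(t+dt) = E u(t) + M c(logR)`` with ``E = expm(A dt)`` and
    ``M = (E - I) A^{-1}`` is exact for piecewise-constant inputs.  The
    returned callable ``step(d, g, logR) -> (d, g)`` is vectorized over
    walker arrays; it is the integrator used inside the run-and-tumble loop.

    quasi_static uses the exact scalar exponential update of its linear
    ``g`` equation; rectified takes four RK4 substeps (its RHS is only
    piecewise-linear).
    """
    p = params
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p.variant in ("feedback", "feedforward"):
        if p.variant == "feedback":
            A = np.array([[-p.omega_d, -p.omega_d * p.alpha], [p.omega / p.d0, 0.0]])

            def c_of(logR):
                return p.omega_d * (p.C + p.mu * logR), -p.omega
        else:
            A = np.array([[-p.omega_d, -p.omega_d * p.alpha], [0.0, -p.omega]])

            def c_of(logR):
                return (
                    p.omega_d * (p.d0 + p.C + p.mu * logR),
                    p.omega * (p.C + p.mu * logR) / p.alpha,
                )

        E = expm(A * dt)
        M = (E - np.eye(2)) @ np.linalg.inv(A)
        e00, e01, e10, e11 = E[0, 0], E[0, 1], E[1, 0], E[1, 1]
        m00, m01, m10, m11 = M[0, 0], M[0, 1], M[1, 0], M[1, 1]

        def step(d, g, logR):
            c0, c1 = c_of(logR)
            d_new = e00 * d + e01 * g + m00 * c0 + m01 * c1
            g_new = e10 * d + e11 * g + m10 * c0 + m11 * c1
            return d_new, g_new

        return step

    if p.variant == "quasi_static":
        # g' = -(omega*alpha/d0) g + omega*((C + mu logR)/d0 - 1)
        k = p.omega * p.alpha / p.d0
        decay = math.exp(-k * dt)

        def step(d, g, logR):
            g_inf = (p.C + p.mu * logR - p.d0) / p.alpha
            g_new = g_inf + (g - g_inf) * decay
            d_new = p.C + p.mu * logR - p.alpha * g_new
            return d_new, g_new

        return step

    # rectified: RK4 substeps on g with algebraic, rectified d
    n_sub = 4
    h = dt / n_sub

    def gdot(g, logR):
        d = np.maximum(0.0, p.C + p.mu * logR - p.alpha * g - p.k_d)
        return p.omega * (d / p.d0 - 1.0)

    def step(d, g, logR):
        for _ in range(n_sub):
            k1 = gdot(g, logR)
            k2 = gdot(g + 0.5 * h * k1, logR)
            k3 = gdot(g + 0.5 * h * k2, logR)
            k4 = gdot(g + h * k3, logR)
            g = g + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        d = np.maximum(0.0, p.C + p.mu * logR - p.alpha * g - p.k_d)
        return d, g

    return step
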