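"""Coarse-grained Langevin dynamics of reward-taxis and its stationary law.

On time scales long compared with a run, the biased run-and-tumble walk is
approximated by the Keller-Segel-type Langevin equation

    dx = chi * grad(log R(x)) dt + sqrt(2 D) dW

with diffusivity ``D ~ v^2 tau / m`` and chemotactic drift
``chi ~ D * mu/d0``.  Its stationary distribution is the power law
``P(x) ∝ R(x)^beta`` with ``beta = chi/D = mu/d0`` — the generalized
matching law, with the matching exponent set purely by circuit-intrinsic
parameters (gain over baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import CircuitParams
from .fields import RewardField
from .taxis import AgentParams, EnsembleResult, Trajectory

__all__ = [
    "LangevinParams",
    "StationaryLaw",
    "coefficients_from_mechanism",
    "run_and_tumble_attenuation",
    "simulate_langevin",
    "ensemble_langevin",
    "stationary_density",
]


@dataclass(frozen=True)
class LangevinParams:
    """Diffusion D (cm^2/s), drift chi (cm^2/s), spatial dimension m."""

    D: float
    chi: float
    m: int = 1

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not math.isfinite(self.chi):
            raise ValueError("chi must be finite")
        if self.m not in (1, 2, 3):
            raise ValueError("m must be 1, 2 or 3")

    @property
    def beta(self) -> float:
        """Matching exponent chi/D."""
        return self.chi / self.D


def coefficients_from_mechanism(agent: AgentParams, circuit: CircuitParams) -> LangevinParams:
    """D = v0^2 tau / m and chi = D * h * mu / d0 from the mechanistic model.

    The speed-gain exponent h multiplies the drift (nonlinear gain
    v ∝ d^h); with h = 1 this reduces to chi = m^-1 v^2 tau mu/d0.
    """
    D = agent.v0**2 * agent.tau / agent.m
    chi = D * agent.h_speed * circuit.mu / circuit.d0
    return LangevinParams(D=D, chi=chi, m=agent.m)


def run_and_tumble_attenuation(agent: AgentParams, circuit: CircuitParams) -> float:
    """Linear-response attenuation of the chemotactic drift at finite rates.

    The coefficient ``chi = m^-1 v^2 tau mu/d0`` is the asymptotic drift for
    runs long compared with the dopamine response and short compared with
    adaptation, ``1/omega_d << tau << d0/(alpha*omega)``.  For the
    speed-modulated walk at finite rates, linear-response analysis of the
    two-ODE circuit in a constant log-gradient gives the multiplicative
    correction

        [omega_d / (omega_d + 1/tau)] * [1 / (1 + alpha*omega*tau/d0)],

    i.e. the effective matching exponent is ``beta * attenuation``.  Valid
    while the circuit's spatial memory ``v * d0/(alpha*omega)`` stays small
    against the field's length scale; for slower adaptation the drift
    becomes nonlocal and the exponent instead overshoots.
    """
    fast = agent.tau * circuit.omega_d / (1.0 + agent.tau * circuit.omega_d)
    slow = 1.0 / (1.0 + circuit.alpha * circuit.omega * agent.tau / circuit.d0)
    return fast * slow


def _drift_fn(field: RewardField, drift: str):
    if drift == "log":
        return field.grad_log
    if drift == "linear":
        # negative control: advection along grad R instead of grad log R
        return field.grad_value
    raise ValueError("drift must be 'log' or 'linear'")


def simulate_langevin(
    params: LangevinParams,
    field: RewardField,
    T: float,
    dt: float,
    seed: int | None = None,
    x_init=None,
    box: tuple[float, float] | None = (-90.0, 90.0),
    drift: str = "log",
) -> Trajectory:
    """Euler-Maruyama path of one particle; returns a Trajectory whose
    circuit/heading channels are filled with placeholders (the coarse-grained
    model has no internal state)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    m = params.m
    n_steps = int(round(T / dt))
    x = np.zeros(m) if x_init is None else np.asarray(x_init, dtype=float).reshape(m)
    grad = _drift_fn(field, drift)
    sig = math.sqrt(2.0 * params.D * dt)

    times = np.arange(n_steps + 1) * dt
    pos = np.empty((n_steps + 1, m))
    pos[0] = x
    for i in range(n_steps):
        xq = x[0] if m == 1 else x
        g = np.asarray(grad(xq), dtype=float).reshape(m)
        if not np.all(np.isfinite(g)):
            raise ValueError("field gradient is not finite along the path")
        x = x + params.chi * g * dt + sig * rng.normal(size=m)
        if box is not None:
            lo, hi = box
            x = np.where(x > hi, 2 * hi - x, x)
            x = np.where(x < lo, 2 * lo - x, x)
        pos[i + 1] = x

    zeros = np.zeros(n_steps + 1)
    headings = np.zeros((n_steps + 1, m))
    headings[:, 0] = 1.0
    return Trajectory(times, pos, headings, np.abs(zeros), zeros, zeros, np.empty(0))


def ensemble_langevin(
    params: LangevinParams,
    field,
    n_walkers: int,
    T: float,
    dt: float,
    seed: int | None = None,
    centers=(30.0, -30.0),
    window: float = 2.5,
    box: tuple[float, float] | None = (-90.0, 90.0),
    burn_in_frac: float = 0.2,
    x0=None,
    bin_edges=None,
    drift: str = "log",
) -> EnsembleResult:
    """Vectorized 1-D Euler-Maruyama batch accumulating window occupancy.

    ``field`` is a RewardField or a pair of callables ``(grad_fn,)`` is not
    accepted — pass a field object, or a callable ``x -> drift gradient``
    (already including the log/linear choice) for per-walker parameters.
    """
    if params.m != 1:
        raise ValueError("ensemble_langevin supports m=1")
    rng = np.random.default_rng(seed)
    grad = _drift_fn(field, drift) if hasattr(field, "grad_log") else field

    n_steps = int(round(T / dt))
    burn_steps = int(burn_in_frac * n_steps)
    x = np.zeros(n_walkers) if x0 is None else np.broadcast_to(np.asarray(x0, float), (n_walkers,)).copy()
    x_start = x.copy()
    sig = math.sqrt(2.0 * params.D * dt)
    centers = np.asarray(centers, dtype=float)
    occ = np.zeros((n_walkers, centers.size))
    hist = None
    if bin_edges is not None:
        bin_edges = np.asarray(bin_edges, dtype=float)
        hist = np.zeros(bin_edges.size - 1)

    for i in range(n_steps):
        x += params.chi * np.asarray(grad(x), dtype=float) * dt + sig * rng.normal(size=n_walkers)
        if box is not None:
            lo, hi = box
            np.copyto(x, 2 * hi - x, where=x > hi)
            np.copyto(x, 2 * lo - x, where=x < lo)
        if i >= burn_steps:
            for k in range(centers.size):
                occ[:, k] += (np.abs(x - centers[k]) <= window) * dt
            if hist is not None:
                idx = np.searchsorted(bin_edges, x) - 1
                valid = (idx >= 0) & (idx < hist.size)
                np.add.at(hist, idx[valid], 1.0)

    return EnsembleResult(occ, (x - x_start) / T, x.copy(), T, hist, bin_edges)


@dataclass
class StationaryLaw:
    """Normalized stationary density P(x) = R(x)^beta / Z on a 1-D domain."""

    beta: float
    grid: np.ndarray
    pdf: np.ndarray
    field: RewardField

    def ratio(self, xa: float, xb: float) -> float:
        """P(xa)/P(xb) = (R(xa)/R(xb))^beta."""
        return float(np.exp(self.beta * (self.field.log_value(xa) - self.field.log_value(xb))))

    def bin_probabilities(self, edges) -> np.ndarray:
        edges = np.asarray(edges, dtype=float)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (self.pdf[1:] + self.pdf[:-1]) * np.diff(self.grid))])
        cdf /= cdf[-1]
        vals = np.interp(edges, self.grid, cdf)
        return np.diff(vals)

    def window_probability(self, center: float, window: float) -> float:
        return float(self.bin_probabilities([center - window, center + window])[0])


def stationary_density(
    params: LangevinParams,
    field: RewardField,
    domain: tuple[float, float] = (-90.0, 90.0),
    n: int = 4001,
) -> StationaryLaw:
    """Closed-form stationary law R(x)^beta normalized by quadrature on ``domain``."""
    lo, hi = domain
    if not hi > lo:
        raise ValueError("domain must be an increasing interval")
    grid = np.linspace(lo, hi, n)
    beta = params.beta
    logp = beta * np.asarray(field.log_value(grid), dtype=float)
    logp -= logp.max()
    p = np.exp(logp)
    Z = np.trapezoid(p, grid)
    if not (math.isfinite(Z) and Z > 0):
        raise ValueError("R(x)^beta is not integrable on the domain")
    return StationaryLaw(beta=beta, grid=grid, pdf=p / Z, field=field)
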