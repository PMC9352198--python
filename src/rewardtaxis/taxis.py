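"""Run-and-tumble navigation modulated by the dopamine circuit.

The agent moves in straight runs at speed ``v`` and reorients ("tumbles") at
random with rate ``1/tau``.  The circuit is driven by the expected-reward
field along the trajectory, ``R(x(t))``, and its dopamine output modulates
either the speed, ``v = v0 * (d/d0)^h`` (default), or the tumble rate,
``1/tau * d0/d``.  Circuit state is carried continuously across tumbles, so
gradient climbing emerges purely from the sensing-movement feedback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import CircuitParams, make_propagator, steady_state
from .fields import RewardField

__all__ = ["AgentParams", "Trajectory", "EnsembleResult", "simulate_taxis", "residence_times", "ensemble_occupancy"]


@dataclass(frozen=True)
class AgentParams:
    """Movement parameters.

    v0: baseline speed at d = d0, cm/s.  tau: mean run duration, s.
    m: spatial dimension.  modulation: 'speed' or 'tumble'.  h_speed: speed
    gain exponent (v = v0 (d/d0)^h).  persistence in [0, 1) blends the new
    heading with the old one (0 = fully random reorientation).
    """

    v0: float = 10.0
    tau: float = 0.1
    m: int = 1
    modulation: str = "speed"
    h_speed: float = 1.0
    persistence: float = 0.0

    def __post_init__(self):
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.m not in (1, 2, 3):
            raise ValueError("dimension m must be 1, 2 or 3")
        if self.modulation not in ("speed", "tumble"):
            raise ValueError("modulation must be 'speed' or 'tumble'")
        if self.h_speed <= 0:
            raise ValueError("h_speed must be positive")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")


@dataclass
class Trajectory:
    """Recorded agent path with aligned circuit state."""

    times: np.ndarray
    positions: np.ndarray  # (n, m) cm
    headings: np.ndarray  # (n, m) unit vectors
    speeds: np.ndarray  # cm/s
    d_series: np.ndarray
    g_series: np.ndarray
    tumble_times: np.ndarray

    def __post_init__(self):
        n = len(self.times)
        if self.positions.shape[0] != n or self.headings.shape[0] != n:
            raise ValueError("trajectory arrays must be aligned")
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be non-negative")

    @property
    def m(self) -> int:
        return self.positions.shape[1]

    def to_frame(self):
        import pandas as pd

        cols = {"t": self.times}
        for j in range(self.m):
            cols[f"x{j}"] = self.positions[:, j]
        for j in range(self.m):
            cols[f"h{j}"] = self.headings[:, j]
        cols["v"] = self.speeds
        cols["d"] = self.d_series
        cols["g"] = self.g_series
        tumbled = np.zeros(len(self.times), dtype=int)
        tumbled[np.searchsorted(self.times, self.tumble_times).clip(0, len(self.times) - 1)] = 1
        cols["tumbled"] = tumbled
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class EnsembleResult:
    """Summary statistics from a batch of walkers (no full paths kept)."""

    occupancy: np.ndarray  # (n_walkers, n_centers) seconds, after burn-in
    drift: np.ndarray  # (n_walkers,) mean velocity (x_T - x_0)/T along axis 0
    final_positions: np.ndarray
    duration: float
    histogram: np.ndarray | None = None
    bin_edges: np.ndarray | None = None


def _unit_headings(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    if m == 1:
        return rng.choice([-1.0, 1.0], size=(n, 1))
    v = rng.normal(size=(n, m))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _field_log(field, x, m):
    if m == 1:
        return field.log_value(x[:, 0])
    return field.log_value(x)


def simulate_taxis(
    agent: AgentParams,
    circuit: CircuitParams,
    field: RewardField,
    T: float,
    dt: float,
    seed: int | None = None,
    x0=None,
    box: tuple[float, float] | None = None,
) -> Trajectory:
    """Simulate one agent for duration ``T`` with step ``dt``, recording the path.

    The circuit starts adapted to ``R(x0)``.  Tumbling is a per-step
    Bernoulli event (rate ``1/tau``, or dopamine-modulated for
    ``modulation='tumble'``); the circuit is advanced with the exact
    piecewise-constant-input propagator.  ``box=(lo, hi)`` applies reflecting
    boundaries on every coordinate; ``None`` leaves the walk unbounded.
    """
    if dt >= agent.tau:
        raise ValueError("dt must be small compared with the run duration tau")
    rng = np.random.default_rng(seed)
    m = agent.m
    n_steps = int(round(T / dt))
    x = np.zeros((1, m)) if x0 is None else np.asarray(x0, dtype=float).reshape(1, m)

    logR0 = float(_field_log(field, x, m)[0])
    st = steady_state(circuit, math.exp(logR0))
    d = np.array([st.d])
    g = np.array([st.g])
    step_circuit = make_propagator(circuit, dt)
    heading = _unit_headings(rng, 1, m)

    times = np.arange(n_steps + 1) * dt
    pos = np.empty((n_steps + 1, m))
    heads = np.empty((n_steps + 1, m))
    speeds = np.empty(n_steps + 1)
    ds = np.empty(n_steps + 1)
    gs = np.empty(n_steps + 1)
    tumbles = []

    base_rate = 1.0 / agent.tau
    for i in range(n_steps + 1):
        pos[i] = x[0]
        heads[i] = heading[0]
        ds[i] = d[0]
        gs[i] = g[0]
        rel = max(d[0], 0.0) / circuit.d0
        if agent.modulation == "speed":
            v = agent.v0 * rel**agent.h_speed
            rate = base_rate
        else:
            v = agent.v0
            rate = base_rate / max(rel, 1e-6)
        speeds[i] = v
        if i == n_steps:
            break
        x = x + v * heading * dt
        if box is not None:
            lo, hi = box
            over = x > hi
            under = x < lo
            x = np.where(over, 2 * hi - x, x)
            x = np.where(under, 2 * lo - x, x)
            heading = np.where(over | under, -heading, heading)
        logR = _field_log(field, x, m)
        d, g = step_circuit(d, g, logR)
        if rng.random() < min(1.0, rate * dt):
            new = _unit_headings(rng, 1, m)
            if agent.persistence > 0:
                new = agent.persistence * heading + (1 - agent.persistence) * new
                new = new / np.linalg.norm(new, axis=1, keepdims=True)
            heading = new
            tumbles.append(times[i + 1])

    return Trajectory(times, pos, heads, speeds, ds, gs, np.asarray(tumbles))


def residence_times(traj: Trajectory, centers, window: float) -> np.ndarray:
    """Total time the trajectory spends within an L-inf ``window`` of each center."""
    if window <= 0:
        raise ValueError("window must be positive")
    if len(traj.times) < 2:
        raise ValueError("trajectory is empty")
    dt = float(np.median(np.diff(traj.times)))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[1] != traj.m:
        centers = centers.reshape(-1, traj.m)
    out = np.empty(centers.shape[0])
    for k, c in enumerate(centers):
        inside = np.all(np.abs(traj.positions - c) <= window, axis=1)
        out[k] = inside.sum() * dt
    return out


def ensemble_occupancy(
    agent: AgentParams,
    circuit: CircuitParams,
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
) -> EnsembleResult:
    """Vectorized 1-D batch of run-and-tumble walkers, accumulating window
    occupancy online instead of recording full paths.

    ``field`` is a RewardField or a callable ``x -> log R(x)`` vectorized
    over walker positions (a callable allows per-walker field parameters, as
    used by the matching harness).  Occupancy is accumulated after the
    burn-in fraction of the run.  Only m=1 and the feedback/feedforward/
    quasi_static circuit variants are supported on this fast path.
    """
    if agent.m != 1:
        raise ValueError("ensemble_occupancy supports m=1 (use simulate_taxis otherwise)")
    if dt >= agent.tau:
        raise ValueError("dt must be small compared with tau")
    rng = np.random.default_rng(seed)
    log_field = field.log_value if hasattr(field, "log_value") else field

    n_steps = int(round(T / dt))
    burn_steps = int(burn_in_frac * n_steps)
    x = np.zeros(n_walkers) if x0 is None else np.broadcast_to(np.asarray(x0, float), (n_walkers,)).copy()
    x_start = x.copy()

    logR = np.asarray(log_field(x), dtype=float)
    # adapted initialization (feedback-style closed form per variant)
    p = circuit
    if p.variant == "feedforward":
        g = (p.C + p.mu * logR) / p.alpha
    else:
        g = (p.C - p.d0 + p.mu * logR) / p.alpha
    d = np.full(n_walkers, p.d0)
    step_circuit = make_propagator(circuit, dt)

    heading = rng.choice([-1.0, 1.0], size=n_walkers)
    centers = np.asarray(centers, dtype=float)
    occ = np.zeros((n_walkers, centers.size))
    hist = None
    if bin_edges is not None:
        bin_edges = np.asarray(bin_edges, dtype=float)
        hist = np.zeros(bin_edges.size - 1)

    base_rate = 1.0 / agent.tau
    for i in range(n_steps):
        rel = np.maximum(d, 0.0) / p.d0
        if agent.modulation == "speed":
            v = agent.v0 * rel**agent.h_speed
            rate = base_rate
        else:
            v = agent.v0
            rate = base_rate / np.maximum(rel, 1e-6)
        x += v * heading * dt
        if box is not None:
            lo, hi = box
            over = x > hi
            under = x < lo
            np.copyto(x, 2 * hi - x, where=over)
            np.copyto(x, 2 * lo - x, where=under)
            np.copyto(heading, -heading, where=over | under)
        logR = np.asarray(log_field(x), dtype=float)
        d, g = step_circuit(d, g, logR)
        tumble = rng.random(n_walkers) < np.minimum(1.0, rate * dt)
        if np.any(tumble):
            heading = np.where(tumble, rng.choice([-1.0, 1.0], size=n_walkers), heading)
        if i >= burn_steps:
            for k in range(centers.size):
                occ[:, k] += (np.abs(x - centers[k]) <= window) * dt
            if hist is not None:
                idx = np.searchsorted(bin_edges, x) - 1
                valid = (idx >= 0) & (idx < hist.size)
                np.add.at(hist, idx[valid], 1.0)

    drift = (x - x_start) / T
    return EnsembleResult(occ, drift, x.copy(), T, hist, bin_edges)
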