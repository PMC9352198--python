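"""Temporal-difference learning of logarithmic values.

The classic tabular TD(0) rule updates V(s) with the prediction error
``r + gamma*V(s') - V(s)``.  A circuit that carries log-transformed values
can learn the same fixed point using only the logarithmic error
``delta_log = log(r + gamma*V(s')) - log V(s)`` via

    log V(s) <- log V(s) + alpha * (exp(delta_log) - 1)

whose expected update vanishes exactly when V(s) = E[r + gamma*V(s')] — the
classic TD fixed point — for any reward distribution.  The chain experiment
walks N states S1..SN with a reward drawn at SN, and checks convergence of
log V(S1) to the analytic discounted value log(gamma^(N-1) * E[r]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "TDParams",
    "LogValueTable",
    "ChainResult",
    "log_td_update",
    "classic_td_update",
    "run_chain_experiment",
    "chain_analytic_target",
]

_REWARD_MODELS = ("deterministic", "normal_cv", "bernoulli")


@dataclass(frozen=True)
class TDParams:
    """Learning configuration.

    ``alpha_lr`` is the learning rate (distinct from the circuit's inhibition
    strength alpha).  ``reward_model`` selects the distribution drawn at the
    final chain state: deterministic, normal with coefficient of variation
    ``cv`` (truncated positive), or Bernoulli with success probability
    ``p_bernoulli`` — all with mean ``magnitude``.
    """

    gamma_disc: float = 0.9
    alpha_lr: float = 0.02
    N: int = 5
    episodes: int = 3000
    reward_model: str = "deterministic"
    magnitude: float = 50.0
    cv: float = 0.3
    p_bernoulli: float = 0.5
    reward_floor_frac: float = 1e-3

    def __post_init__(self):
        if not (0.0 < self.gamma_disc < 1.0):
            raise ValueError("gamma_disc must be in (0, 1)")
        if not (0.0 < self.alpha_lr < 1.0):
            raise ValueError("alpha_lr must be in (0, 1)")
        if self.N < 2:
            raise ValueError("need at least 2 chain states")
        if self.reward_model not in _REWARD_MODELS:
            raise ValueError(f"reward_model must be one of {_REWARD_MODELS}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")


@dataclass
class LogValueTable:
    """Per-state log V estimates for non-terminal states."""

    logv: np.ndarray

    @classmethod
    def zeros(cls, n_states: int) -> "LogValueTable":
        return cls(np.zeros(n_states))

    def value(self, s: int) -> float:
        return float(math.exp(self.logv[s]))


def log_td_update(table: LogValueTable, s: int, s_prime: int | None, r: float, params: TDParams) -> LogValueTable:
    """One logarithmic TD update of state ``s``.

    ``s_prime=None`` marks a transition into the terminal (post-reward)
    state, whose value is zero by convention, so the target is ``r`` alone.
    """
    target = r if s_prime is None else r + params.gamma_disc * math.exp(table.logv[s_prime])
    if not target > 0:
        raise ValueError("r + gamma*V(s') must be positive for the logarithmic rule")
    delta_log = math.log(target) - table.logv[s]
    table.logv[s] += params.alpha_lr * (math.exp(delta_log) - 1.0)
    return table


def classic_td_update(vtable: np.ndarray, s: int, s_prime: int | None, r: float, params: TDParams) -> np.ndarray:
    """Classic TD(0): V(s) <- V(s) + alpha*(r + gamma*V(s') - V(s))."""
    target = r if s_prime is None else r + params.gamma_disc * vtable[s_prime]
    vtable[s] += params.alpha_lr * (target - vtable[s])
    return vtable


def _draw_reward(params: TDParams, rng: np.random.Generator) -> float:
    if params.reward_model == "deterministic":
        return params.magnitude
    if params.reward_model == "normal_cv":
        sd = params.cv * params.magnitude
        for _ in range(1000):
            r = rng.normal(params.magnitude, sd)
            if r > 0:
                return float(r)
        raise RuntimeError("failed to draw a positive normal reward")
    # bernoulli with mean `magnitude`: magnitude/p with prob p, else a small
    # positive floor that keeps the logarithmic target defined
    if rng.random() < params.p_bernoulli:
        return params.magnitude / params.p_bernoulli
    return params.reward_floor_frac * params.magnitude


def chain_analytic_target(params: TDParams) -> float:
    """log of the discounted value at S1: log(gamma^(N-1) * E[r])."""
    mean_r = params.magnitude
    if params.reward_model == "bernoulli":
        mean_r = params.magnitude + (1.0 - params.p_bernoulli) * params.reward_floor_frac * params.magnitude
    return math.log(params.gamma_disc ** (params.N - 1) * mean_r)


@dataclass
class ChainResult:
    """Learning curve and analytic target of the chain experiment."""

    log_v1_curve: np.ndarray
    table: LogValueTable
    analytic_target: float
    params: TDParams = dc_field(repr=False, default=None)

    @property
    def converged_log_v1(self) -> float:
        """Mean of the final 10% of the learning curve."""
        tail = max(1, self.log_v1_curve.size // 10)
        return float(self.log_v1_curve[-tail:].mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "episode": np.arange(1, self.log_v1_curve.size + 1),
                "log_v1": self.log_v1_curve,
                "analytic_target": self.analytic_target,
            }
        )


def run_chain_experiment(params: TDParams, seed: int | None = None, init_logv: float = 0.0) -> ChainResult:
    """Repeated episodes through the S1..SN chain with the logarithmic rule.

    Each episode steps deterministically S1 -> ... -> SN (zero reward) and
    ends with the reward draw at SN (terminal transition).  Returns the
    per-episode trajectory of log V(S1) together with the analytic target.
    """
    rng = np.random.default_rng(seed)
    table = LogValueTable(np.full(params.N, float(init_logv)))
    curve = np.empty(params.episodes)
    for ep in range(params.episodes):
        for s in range(params.N - 1):
            log_td_update(table, s, s + 1, 0.0, params)
        r = _draw_reward(params, rng)
        log_td_update(table, params.N - 1, None, r, params)
        curve[ep] = table.logv[0]
    return ChainResult(curve, table, chain_analytic_target(params), params)
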