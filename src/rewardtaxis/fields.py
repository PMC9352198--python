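"""Expected-reward inputs: temporal signals, spatial fields, and value helpers.

Expected reward ``R`` is the immediate reward plus the discounted value of
the successor state, ``R = r + V(s')``.  The circuit is driven by ``log R``,
so every construction here guarantees strict positivity, and spatial fields
expose an analytic log-gradient (the quantity the coarse-grained Langevin
drift uses).  Units of ``R`` are arbitrary throughout: only ratios matter to
a fold-change detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RewardSignal",
    "RewardField",
    "UniformField",
    "GaussianMixtureField",
    "ExpDecayField",
    "LogLinearField",
    "CueRewardSchedule",
    "DiscountedValueSpec",
    "make_step",
    "make_cue_reward",
    "make_gaussian_field",
    "make_expdecay_field",
    "make_shifted_pair_schedule",
    "expected_reward_at_delay",
    "delay_fold_ratio",
    "parse_field_spec",
    "parse_signal_spec",
]


@dataclass(frozen=True)
class RewardSignal:
    """Positive scalar signal R(t) with a list of jump times.

    ``fn`` must be vectorized over ``t``.  The discontinuity list lets the
    circuit integrator restart exactly at each jump.
    """

    fn: Callable
    discontinuities: tuple = ()

    def __call__(self, t):
        return self.fn(np.asarray(t, dtype=float))

    def log(self, t):
        return np.log(self(t))

    def scaled(self, lam: float) -> "RewardSignal":
        """The signal multiplied by a constant factor (for FCD checks)."""
        if lam <= 0:
            raise ValueError("scale factor must be positive")
        inner = self.fn
        return RewardSignal(lambda t: lam * inner(t), self.discontinuities)


def make_step(R0: float, lam: float, t0: float = 0.0) -> RewardSignal:
    """Step input R(t) = R0 + lam * theta(t - t0)."""
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    if R0 + lam <= 0:
        raise ValueError("post-step reward R0 + lam must be positive")
    return RewardSignal(
        lambda t: np.where(t >= t0, R0 + lam, R0),
        (float(t0),),
    )


@dataclass(frozen=True)
class CueRewardSchedule:
    """One cue -> reward trial.

    A cue at ``t_cue`` predicts with probability ``p`` a reward of magnitude
    ``u``; expected reward steps from the pre-cue baseline ``R_pre`` to
    ``p*(b + lam*u)`` and, at ``t_reward``, to ``b + lam*u`` if delivered
    (a 1/p fold change, independent of ``u``) or back to ``R_pre`` on
    omission.
    """

    u: float
    p: float = 0.5
    b: float = 2.0
    lam: float = 10.0
    R_pre: float = 1.0
    t_cue: float = 1.0
    t_reward: float = 2.0
    delivered: bool = True

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError("delivery probability p must be in (0, 1]")
        if self.R_pre <= 0:
            raise ValueError("pre-cue baseline must be positive")
        if self.reward_level <= 0:
            raise ValueError("b + lam*u must be positive")
        if not self.t_reward > self.t_cue:
            raise ValueError("reward time must follow cue time")

    @property
    def cue_level(self) -> float:
        return self.p * (self.b + self.lam * self.u)

    @property
    def reward_level(self) -> float:
        return self.b + self.lam * self.u

    @property
    def fold_change_at_delivery(self) -> float:
        """reward_level / cue_level = 1/p, independent of u."""
        return self.reward_level / self.cue_level


def make_cue_reward(schedule: CueRewardSchedule) -> RewardSignal:
    s = schedule
    post = s.reward_level if s.delivered else s.R_pre

    def fn(t):
        t = np.asarray(t, dtype=float)
        return np.select(
            [t < s.t_cue, t < s.t_reward], [s.R_pre, s.cue_level], default=post
        )

    return RewardSignal(fn, (s.t_cue, s.t_reward))


def expected_reward_at_delay(y: float, p: float, gamma_disc: float, dt_steps: float) -> float:
    """Expected reward p * gamma^dt * y of a reward y delivered with
    probability p, dt_steps into the future."""
    if y <= 0:
        raise ValueError("reward magnitude must be positive")
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    if not (0.0 < gamma_disc < 1.0):
        raise ValueError("discount factor must be in (0, 1)")
    return p * gamma_disc**dt_steps * y


def delay_fold_ratio(p: float, gamma_disc: float, dt_steps: float) -> float:
    """Fold change R(dt)/R(0) = 1/(p*gamma^dt) on delivery — independent of
    reward magnitude, the engine of scale-invariant delivery responses."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    if not (0.0 < gamma_disc <= 1.0):
        raise ValueError("discount factor must be in (0, 1]")
    return 1.0 / (p * gamma_disc**dt_steps)


def make_shifted_pair_schedule(
    X: float,
    Y: float,
    p_alt: float = 0.5,
    n_trials: int = 10,
    R_pre: float = 0.5,
    t_cue: float = 1.0,
    t_reward: float = 2.0,
    seed: int | None = None,
):
    """Trials alternating rewards of magnitude X+Y and X-Y after a common cue.

    The cue predicts that *some* reward will arrive, so expected reward steps
    to the mean magnitude ``X``; delivery steps it to the drawn magnitude.
    Returns ``(magnitudes, signals)`` where each signal is the trial's
    ``R(t)``.  With a fold-change detector the delivery response scales as
    ``log((X±Y)/X)``, so responses shrink as ``X`` grows at fixed ``Y``.
    """
    if not (X > Y > 0):
        raise ValueError("need X > Y > 0 so both magnitudes are positive")
    rng = np.random.default_rng(seed)
    highs = rng.random(n_trials) < p_alt
    mags = np.where(highs, X + Y, X - Y)
    signals = []
    for r in mags:
        def fn(t, r=float(r)):
            t = np.asarray(t, dtype=float)
            return np.select([t < t_cue, t < t_reward], [R_pre, X], default=r)

        signals.append(RewardSignal(fn, (t_cue, t_reward)))
    return mags, signals


# ---------------------------------------------------------------------------
# spatial fields


class RewardField:
    """Positive field R(x) with analytic log-gradient.

    ``x`` may be a scalar (1-D fields), an ``(m,)`` point, or an ``(n, m)``
    batch.  Subclasses implement ``log_value`` and ``grad_log``; ``value``
    and ``grad_value`` derive from them.
    """

    m: int = 1

    def log_value(self, x):
        raise NotImplementedError

    def value(self, x):
        return np.exp(self.log_value(x))

    def grad_log(self, x):
        raise NotImplementedError

    def grad_value(self, x):
        """dR/dx — used only by the non-logarithmic (negative-control) drift."""
        lv = self.log_value(x)
        return np.exp(lv) * self.grad_log(x)


@dataclass(frozen=True)
class UniformField(RewardField):
    """Constant field; dimension-agnostic (grad log R = 0)."""

    R0: float = 1.0
    m: int = 1

    def __post_init__(self):
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")

    def log_value(self, x):
        x = np.asarray(x, dtype=float)
        shape = x.shape[:-1] if (self.m > 1 and x.ndim > 0) else x.shape
        return np.full(shape, math.log(self.R0))

    def grad_log(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class GaussianMixtureField(RewardField):
    """Two-peak 1-D field R(x) = R1 exp(-(x-x1)^2/2 b1^2) + R2 exp(-(x-x2)^2/2 b2^2).

    The default uses equal widths ``b`` for both peaks; ``asymmetric=True``
    reproduces the alternative form in which the first peak has width ``2b``.
    Evaluation goes through log-sum-exp so the far tails never underflow.
    """

    R1: float = 1.0
    R2: float = 1.0
    x1: float = 30.0
    x2: float = -30.0
    b: float = 10.0
    asymmetric: bool = False
    m: int = 1

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("peak rewards must be positive")
        if self.b <= 0:
            raise ValueError("width b must be positive")

    @property
    def b1(self) -> float:
        return 2.0 * self.b if self.asymmetric else self.b

    @property
    def b2(self) -> float:
        return self.b

    def _terms(self, x):
        x = np.asarray(x, dtype=float)
        z1 = (x - self.x1) / self.b1
        z2 = (x - self.x2) / self.b2
        a1 = math.log(self.R1) - 0.5 * z1**2
        a2 = math.log(self.R2) - 0.5 * z2**2
        return x, z1, z2, a1, a2

    def log_value(self, x):
        _, _, _, a1, a2 = self._terms(x)
        return np.logaddexp(a1, a2)

    def grad_log(self, x):
        _, z1, z2, a1, a2 = self._terms(x)
        # softmax weights of the two mixture components
        w1 = 1.0 / (1.0 + np.exp(a2 - a1))
        w2 = 1.0 - w1
        return -(w1 * z1 / self.b1 + w2 * z2 / self.b2)


@dataclass(frozen=True)
class ExpDecayField(RewardField):
    """Decaying approach-axis field R(x) = exp(-gamma * x^h), defined for x >= 0."""

    gamma_field: float = 0.04
    h_field: float = 1.5
    m: int = 1

    def __post_init__(self):
        if self.gamma_field <= 0 or self.h_field <= 0:
            raise ValueError("gamma_field and h_field must be positive")

    def _check(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("ExpDecayField is defined on the approach axis x >= 0")
        return x

    def log_value(self, x):
        x = self._check(x)
        return -self.gamma_field * x**self.h_field

    def grad_log(self, x):
        x = self._check(x)
        return -self.gamma_field * self.h_field * x ** (self.h_field - 1.0)


@dataclass(frozen=True)
class LogLinearField(RewardField):
    """Field with constant log-gradient: log R(x) = slope * x (1-D).

    Useful for measuring the chemotactic drift, which should equal
    ``chi * slope`` everywhere.
    """

    slope: float = 0.01
    m: int = 1

    def log_value(self, x):
        return self.slope * np.asarray(x, dtype=float)

    def grad_log(self, x):
        return np.full_like(np.asarray(x, dtype=float), self.slope)


def make_gaussian_field(R1, R2, x1=30.0, x2=-30.0, b=10.0, asymmetric=False) -> GaussianMixtureField:
    return GaussianMixtureField(R1=R1, R2=R2, x1=x1, x2=x2, b=b, asymmetric=asymmetric)


def make_expdecay_field(gamma_field: float = 0.04, h_field: float = 1.5) -> ExpDecayField:
    return ExpDecayField(gamma_field=gamma_field, h_field=h_field)


@dataclass(frozen=True)
class DiscountedValueSpec:
    """Value function V = E[sum_t gamma^t r_t] for an explicit reward sequence."""

    gamma_disc: float
    rewards: Sequence[float] = dc_field(default_factory=tuple)

    def __post_init__(self):
        if not (0.0 < self.gamma_disc < 1.0):
            raise ValueError("discount factor must be in (0, 1)")

    def value(self) -> float:
        g = self.gamma_disc
        return float(sum(r * g**t for t, r in enumerate(self.rewards)))


# ---------------------------------------------------------------------------
# input-spec mini-grammar used by config files and the CLI


def _floats(body: str) -> list[float]:
    return [float(tok) for tok in body.split(",") if tok.strip() != ""]


def parse_signal_spec(spec: str) -> RewardSignal:
    """Parse ``step:R0,lam,t0`` or ``cue_reward:u,p,b,lam,t_cue,t_rew,delivered``."""
    kind, _, body = spec.partition(":")
    kind = kind.strip()
    if kind == "step":
        R0, lam, t0 = _floats(body)
        return make_step(R0, lam, t0)
    if kind == "cue_reward":
        vals = _floats(body)
        u, p, b, lam, t_cue, t_rew = vals[:6]
        delivered = bool(vals[6]) if len(vals) > 6 else True
        return make_cue_reward(
            CueRewardSchedule(u=u, p=p, b=b, lam=lam, t_cue=t_cue, t_reward=t_rew, delivered=delivered)
        )
    raise ValueError(f"unknown signal spec kind {kind!r}")


def parse_field_spec(spec: str) -> RewardField:
    """Parse ``gauss2:R1,R2,x1,x2,b``, ``expdecay:gamma,h`` or ``uniform:R0``."""
    kind, _, body = spec.partition(":")
    kind = kind.strip()
    if kind == "gauss2":
        R1, R2, x1, x2, b = _floats(body)
        return make_gaussian_field(R1, R2, x1, x2, b)
    if kind == "expdecay":
        gamma_field, h_field = _floats(body)
        return make_expdecay_field(gamma_field, h_field)
    if kind == "uniform":
        (R0,) = _floats(body)
        return UniformField(R0=R0)
    raise ValueError(f"unknown field spec kind {kind!r}")
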