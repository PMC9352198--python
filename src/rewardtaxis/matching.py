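"""Matching-law experiment harness.

Sweeps the reward ratio R1/R2 of a two-peak field, measures residence-time
ratios in windows around the peaks, and fits the generalized matching law

    P(x1)/P(x2) = k * (R1/R2)^beta

by ordinary least squares on logs.  The reward-taxis theory predicts
beta = mu/d0 regardless of movement speed or run duration.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from .circuit import CircuitParams
from .fields import GaussianMixtureField
from .langevin import coefficients_from_mechanism, ensemble_langevin
from .taxis import AgentParams, ensemble_occupancy

__all__ = ["MatchingExperimentSpec", "MatchingResult", "fit_matching_law", "run_matching_experiment"]

DEFAULT_RATIOS = (1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class MatchingExperimentSpec:
    """Protocol for a matching sweep on the double-Gaussian field.

    R1 is varied as ``ratio * R2`` with R2 fixed; occupancy is the time spent
    within ``window`` cm (L-inf) of each peak, pooled over replicates.
    """

    ratios: tuple = DEFAULT_RATIOS
    R2: float = 1.0
    x1: float = 30.0
    x2: float = -30.0
    b: float = 10.0
    n_replicates: int = 10
    T: float = 1500.0
    dt: float = 0.01
    window: float = 2.5
    box: tuple = (-90.0, 90.0)
    burn_in_frac: float = 0.2
    bias: float = 1.0  # multiplicative preference bias applied to R1

    def __post_init__(self):
        if len(self.ratios) < 3:
            raise ValueError("need at least 3 reward ratios for the regression")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("reward ratios must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def field_for(self, ratio: float) -> GaussianMixtureField:
        return GaussianMixtureField(
            R1=self.bias * ratio * self.R2, R2=self.R2, x1=self.x1, x2=self.x2, b=self.b
        )


@dataclass
class MatchingResult:
    """Fitted sensitivity and bias of the generalized matching law."""

    beta_hat: float
    k_hat: float
    stderr_beta: float
    stderr_logk: float
    ci95_beta: tuple
    ratios: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    occupancy_ratios: np.ndarray = dc_field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "beta_hat": self.beta_hat,
            "k_hat": self.k_hat,
            "stderr_beta": self.stderr_beta,
            "stderr_logk": self.stderr_logk,
            "ci95_beta": list(self.ci95_beta),
            "ratios": list(map(float, self.ratios)),
            "occupancy_ratios": list(map(float, self.occupancy_ratios)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_matching_law(ratios, occupancy_ratios) -> MatchingResult:
    """OLS of log occupancy ratio on log reward ratio.

    Returns the slope (beta_hat), exponentiated intercept (k_hat), standard
    errors and the 95% CI of the slope.
    """
    ratios = np.asarray(ratios, dtype=float)
    occ = np.asarray(occupancy_ratios, dtype=float)
    if ratios.size != occ.size:
        raise ValueError("ratios and occupancy_ratios must align")
    if ratios.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(ratios <= 0) or np.any(occ <= 0):
        raise ValueError("ratios and occupancies must be positive")
    lx, ly = np.log(ratios), np.log(occ)
    res = stats.linregress(lx, ly)
    n = ratios.size
    tcrit = stats.t.ppf(0.975, n - 2)
    return MatchingResult(
        beta_hat=float(res.slope),
        k_hat=float(math.exp(res.intercept)),
        stderr_beta=float(res.stderr),
        stderr_logk=float(res.intercept_stderr),
        ci95_beta=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        ratios=ratios,
        occupancy_ratios=occ,
    )


def run_matching_experiment(
    spec: MatchingExperimentSpec,
    agent: AgentParams,
    circuit: CircuitParams,
    engine: str = "taxis",
    seed: int | None = None,
) -> MatchingResult:
    """Run the sweep with the run-and-tumble agent or its Langevin coarse-graining.

    Replicates for a given ratio are run as a vectorized walker batch; the
    per-ratio occupancy ratio pools time over replicates.  Ratios whose weak
    window was never visited are dropped with a warning (undersampled).
    """
    if engine not in ("taxis", "langevin"):
        raise ValueError("engine must be 'taxis' or 'langevin'")
    rng = np.random.default_rng(seed)
    centers = (spec.x1, spec.x2)
    kept_ratios, occ_ratios = [], []
    for ratio in spec.ratios:
        fld = spec.field_for(ratio)
        sub = int(rng.integers(2**31))
        if engine == "taxis":
            res = ensemble_occupancy(
                agent,
                circuit,
                fld,
                n_walkers=spec.n_replicates,
                T=spec.T,
                dt=spec.dt,
                seed=sub,
                centers=centers,
                window=spec.window,
                box=spec.box,
                burn_in_frac=spec.burn_in_frac,
            )
        else:
            lp = coefficients_from_mechanism(agent, circuit)
            res = ensemble_langevin(
                lp,
                fld,
                n_walkers=spec.n_replicates,
                T=spec.T,
                dt=spec.dt,
                seed=sub,
                centers=centers,
                window=spec.window,
                box=spec.box,
                burn_in_frac=spec.burn_in_frac,
            )
        t1, t2 = res.occupancy.sum(axis=0)
        if t1 <= 0 or t2 <= 0:
            warnings.warn(
                f"ratio {ratio:g}: empty occupancy window (undersampled replicate); dropped",
                stacklevel=2,
            )
            continue
        kept_ratios.append(ratio)
        occ_ratios.append(t1 / t2)
    return fit_matching_law(kept_ratios, occ_ratios)
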