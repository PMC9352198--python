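"""Logarithmic dose-response fitting.

Phasic dopamine responses to rewards of magnitude ``u`` follow
``delta_d = mu * log(a*u + b)`` (natural log; the base only rescales ``mu``).
When the reward is preceded by a predictive cue the response is the same
curve minus a constant (subtractive GABAergic inhibition).  This module fits
the three (or four, with cued rows) parameters by nonlinear least squares
and generates synthetic response tables for recovery studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ResponseTable",
    "LogResponseFit",
    "fit_log_response",
    "generate_synthetic_responses",
    "DEFAULT_U_GRID",
]

#: Seven-magnitude reward ladder (µl) used as the default synthetic design.
DEFAULT_U_GRID = (0.1, 0.3, 1.2, 2.5, 5.0, 10.0, 20.0)


@dataclass
class ResponseTable:
    """Reward-magnitude / response table with optional SEM and cued flags."""

    data: pd.DataFrame  # columns: u, delta_d, sem (may be NaN), cued (bool)

    def __post_init__(self):
        required = {"u", "delta_d", "cued"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if "sem" not in self.data.columns:
            self.data = self.data.assign(sem=np.nan)
        if (self.data["u"] < 0).any():
            raise ValueError("reward magnitudes must be non-negative")
        if not np.all(np.isfinite(self.data["delta_d"])):
            raise ValueError("responses must be finite")

    @classmethod
    def from_csv(cls, path) -> "ResponseTable":
        df = pd.read_csv(path)
        if "cued" in df.columns:
            df["cued"] = df["cued"].astype(bool)
        else:
            df["cued"] = False
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")

    @property
    def uncued(self) -> pd.DataFrame:
        return self.data[~self.data["cued"]]

    @property
    def cued(self) -> pd.DataFrame:
        return self.data[self.data["cued"]]


@dataclass
class LogResponseFit:
    """Best-fit parameters of delta_d = mu*log(a*u + b) [- sub_const if cued]."""

    a_fit: float
    b_fit: float
    mu_fit: float
    sub_const: float | None
    r2: float
    stderr: dict
    converged: bool = True
    message: str = ""

    def predict(self, u, cued: bool = False):
        out = self.mu_fit * np.log(self.a_fit * np.asarray(u, dtype=float) + self.b_fit)
        if cued:
            if self.sub_const is None:
                raise ValueError("fit has no cued component")
            out = out - self.sub_const
        return out

    def to_dict(self) -> dict:
        return {
            "a": self.a_fit,
            "b": self.b_fit,
            "mu": self.mu_fit,
            "sub_const": self.sub_const,
            "r2": self.r2,
            "stderr": self.stderr,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def generate_synthetic_responses(
    a: float = 0.5,
    b: float = 1.5,
    mu: float = 4.9,
    sub_const: float | None = 3.2,
    u_grid=DEFAULT_U_GRID,
    noise_sd: float = 0.0,
    n_rep: int = 1,
    seed: int | None = None,
) -> ResponseTable:
    """Seed-deterministic table of uncued (and optionally cued) responses.

    Truth model: uncued = mu*log(a*u + b); cued = uncued - sub_const; i.i.d.
    Gaussian noise of SD ``noise_sd`` (spikes/s) on every row.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    u = np.tile(np.asarray(u_grid, dtype=float), n_rep)
    rows = []
    clean = mu * np.log(a * u + b)
    rows.append(pd.DataFrame({"u": u, "delta_d": clean, "cued": False}))
    if sub_const is not None:
        rows.append(pd.DataFrame({"u": u, "delta_d": clean - sub_const, "cued": True}))
    df = pd.concat(rows, ignore_index=True)
    if noise_sd > 0:
        df["delta_d"] = df["delta_d"] + rng.normal(0.0, noise_sd, size=len(df))
    df["sem"] = noise_sd if noise_sd > 0 else np.nan
    return ResponseTable(df)


def _initial_guesses(u, y, with_cue, rng):
    u_pos = u[u > 0]
    a0 = 1.0 / float(np.median(u_pos)) if u_pos.size else 1.0
    b0 = 1.5
    span = float(np.ptp(y)) if np.ptp(y) > 0 else 1.0
    mu0 = span / max(math.log(a0 * u.max() + b0) - math.log(b0), 1e-3)
    base = [a0, b0, mu0] + ([1.0] if with_cue else [])
    yield np.array(base)
    for _ in range(4):
        jitter = rng.lognormal(0.0, 0.5, size=len(base))
        yield np.array(base) * jitter


def fit_log_response(table: ResponseTable, seed: int = 0) -> LogResponseFit:
    """Multi-start nonlinear least squares of the logarithmic response curve.

    Uncued rows constrain (a, b, mu); cued rows, if present, additionally
    constrain a single subtraction constant.  Rows with a finite SEM are
    weighted by 1/SEM.  Standard errors come from the Jacobian at the
    optimum; r^2 is 1 - SS_res/SS_tot over all fitted rows.
    """
    df = table.data
    n_params = 4 if (df["cued"].any()) else 3
    if df["u"].nunique() < n_params:
        raise ValueError(
            f"need at least {n_params} distinct magnitudes to fit {n_params} parameters"
        )
    if not (~df["cued"]).any():
        raise ValueError("uncued rows are required to anchor the curve")
    u = df["u"].to_numpy(dtype=float)
    y = df["delta_d"].to_numpy(dtype=float)
    cued = df["cued"].to_numpy(dtype=bool)
    sem = df["sem"].to_numpy(dtype=float)
    w = np.where(np.isfinite(sem) & (sem > 0), 1.0 / sem, 1.0)
    with_cue = bool(cued.any())

    def residuals(theta):
        a, b, mu = theta[:3]
        pred = mu * np.log(a * u + b)
        if with_cue:
            pred = pred - theta[3] * cued
        return w * (pred - y)

    lo = [1e-9, 1e-9, -np.inf] + ([-np.inf] if with_cue else [])
    hi = [np.inf] * len(lo)
    rng = np.random.default_rng(seed)
    best = None
    for x0 in _initial_guesses(u, y, with_cue, rng):
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    resid = residuals(best.x)
    dof = max(1, len(y) - len(best.x))
    s2 = float(resid @ resid) / dof
    JtJ = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(JtJ) * s2
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(len(best.x), np.nan)
    ss_res = float(np.sum((residuals(best.x) / w) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    names = ["a", "b", "mu"] + (["sub_const"] if with_cue else [])
    return LogResponseFit(
        a_fit=float(best.x[0]),
        b_fit=float(best.x[1]),
        mu_fit=float(best.x[2]),
        sub_const=float(best.x[3]) if with_cue else None,
        r2=r2,
        stderr=dict(zip(names, map(float, se))),
        converged=bool(best.success),
        message=best.message,
    )
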