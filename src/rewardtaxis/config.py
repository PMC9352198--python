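"""Configuration loading, experiment dispatch, seeded RNG management.

A run is described by a flat YAML config naming an experiment, a seed, and
optional parameter overrides (circuit keys mirror the standard names:
omega_d, omega, C, mu, alpha, d0).  Every stochastic experiment is
reproducible from (config, seed): a single top-level RNG is seeded once and
child streams are derived per module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibrate import fit_log_response, generate_synthetic_responses
from .circuit import PRESETS, CircuitParams, response_amplitude, simulate
from .fields import CueRewardSchedule, ExpDecayField, make_cue_reward, make_step
from .langevin import coefficients_from_mechanism, ensemble_langevin, stationary_density
from .matching import MatchingExperimentSpec, run_matching_experiment
from .taxis import AgentParams
from .tdlearn import TDParams, run_chain_experiment

__all__ = ["RunConfig", "load_config", "run_experiment", "EXPERIMENTS"]

_TOP_KEYS = {"experiment", "seed", "out", "circuit", "agent", "options", "verbosity"}
_CIRCUIT_KEYS = {"preset", "omega_d", "omega", "C", "mu", "alpha", "d0", "variant", "k_d"}
_AGENT_KEYS = {"v0", "tau", "m", "modulation", "h_speed", "persistence"}

EXPERIMENTS = (
    "circuit-step",
    "scale-invariance",
    "s1-perturbations",
    "matching",
    "langevin-stationary",
    "td-chain",
    "response-fit",
)


@dataclass
class RunConfig:
    """Validated run description with defaults applied."""

    experiment: str
    seed: int = 0
    out: str = "results"
    circuit: CircuitParams = dc_field(default_factory=CircuitParams)
    agent: AgentParams = dc_field(default_factory=AgentParams)
    options: dict = dc_field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )

    def digest(self) -> str:
        blob = json.dumps(
            {
                "experiment": self.experiment,
                "seed": self.seed,
                "circuit": dataclasses.asdict(self.circuit),
                "agent": dataclasses.asdict(self.agent),
                "options": self.options,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_circuit(section: dict) -> CircuitParams:
    unknown = set(section) - _CIRCUIT_KEYS
    if unknown:
        raise ValueError(f"unknown circuit keys: {sorted(unknown)}")
    base = PRESETS[section.get("preset", "mouse")]
    overrides = {k: v for k, v in section.items() if k != "preset"}
    return dataclasses.replace(base, **overrides)


def _build_agent(section: dict) -> AgentParams:
    unknown = set(section) - _AGENT_KEYS
    if unknown:
        raise ValueError(f"unknown agent keys: {sorted(unknown)}")
    return AgentParams(**section)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are an error."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "experiment" not in raw:
        raise ValueError("config must name an 'experiment'")
    return RunConfig(
        experiment=raw["experiment"],
        seed=int(raw.get("seed", 0)),
        out=str(raw.get("out", "results")),
        circuit=_build_circuit(raw.get("circuit", {}) or {}),
        agent=_build_agent(raw.get("agent", {}) or {}),
        options=dict(raw.get("options", {}) or {}),
        verbosity=int(raw.get("verbosity", 1)),
    )


def _grid(t_end: float, dt: float) -> np.ndarray:
    return np.arange(0.0, t_end + 0.5 * dt, dt)


def _exp_circuit_step(cfg: RunConfig, rng, out: Path) -> dict:
    o = cfg.options
    sig = make_step(o.get("R0", 1.0), o.get("lam", 7.0), o.get("t0", 1.0))
    t = _grid(o.get("t_end", 10.0), o.get("dt", 0.001))
    trace = simulate(cfg.circuit, sig, t)
    trace.to_csv(out / "circuit_step.csv")
    return {
        "d_final": float(trace.d_series[-1]),
        "g_final": float(trace.g_series[-1]),
        "peak_response": response_amplitude(trace, (o.get("t0", 1.0), t[-1])),
    }


def _exp_scale_invariance(cfg: RunConfig, rng, out: Path) -> dict:
    o = cfg.options
    magnitudes = o.get("magnitudes", [0.05, 0.15, 0.5])
    p = o.get("p", 0.5)
    t_cue, t_rew = o.get("t_cue", 1.0), o.get("t_reward", 21.0)
    rows = []
    for u in magnitudes:
        sched = CueRewardSchedule(u=u, p=p, b=o.get("b", 2.0), lam=o.get("lam", 10.0), t_cue=t_cue, t_reward=t_rew)
        t = _grid(t_rew + 5.0, o.get("dt", 0.001))
        trace = simulate(cfg.circuit, make_cue_reward(sched), t)
        rows.append(
            {
                "u": u,
                "cue_response": response_amplitude(trace, (t_cue, 0.5 * (t_cue + t_rew))),
                "delivery_response": response_amplitude(trace, (t_rew, t[-1])),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "scale_invariance.csv", index=False)
    return {"responses": rows}


def _exp_s1_perturbations(cfg: RunConfig, rng, out: Path) -> dict:
    """Movement along an exponentially decaying approach field with speed
    perturbations (pause and speed-up), mimicking controlled-approach
    experiments: dopamine tracks the temporal log-derivative of R(x(t))."""
    o = cfg.options
    field = ExpDecayField(o.get("gamma_field", 0.04), o.get("h_field", 1.5))
    v0 = o.get("v0", 1.0)
    x_start = o.get("x_start", 30.0)
    dt = o.get("dt", 0.001)
    # piecewise speed profile: approach, pause, fast approach
    segs = o.get("segments", [(10.0, v0), (5.0, 0.0), (10.0, 2.0 * v0)])
    times = [0.0]
    xs = [x_start]
    for dur, v in segs:
        n = int(round(dur / dt))
        for _ in range(n):
            times.append(times[-1] + dt)
            xs.append(max(0.0, xs[-1] - v * dt))
    times, xs = np.asarray(times), np.asarray(xs)
    Rvals = field.value(xs)

    class _Sig:
        discontinuities = tuple(np.cumsum([d for d, _ in segs])[:-1])

        def __call__(self, t):
            return np.interp(t, times, Rvals)

    trace = simulate(cfg.circuit, _Sig(), times[:: max(1, int(0.01 / dt))])
    trace.to_csv(out / "s1_perturbations.csv")
    return {"d_range": [float(trace.d_series.min()), float(trace.d_series.max())]}


def _exp_matching(cfg: RunConfig, rng, out: Path) -> dict:
    o = dict(cfg.options)
    engine = o.pop("engine", "taxis")
    spec_kwargs = {k: v for k, v in o.items() if k in MatchingExperimentSpec.__dataclass_fields__}
    if "ratios" in spec_kwargs:
        spec_kwargs["ratios"] = tuple(spec_kwargs["ratios"])
    if "box" in spec_kwargs:
        spec_kwargs["box"] = tuple(spec_kwargs["box"])
    spec = MatchingExperimentSpec(**spec_kwargs)
    res = run_matching_experiment(spec, cfg.agent, cfg.circuit, engine=engine, seed=int(rng.integers(2**31)))
    res.to_json(out / "matching.json")
    return res.to_dict()


def _exp_langevin_stationary(cfg: RunConfig, rng, out: Path) -> dict:
    from .fields import GaussianMixtureField

    o = cfg.options
    field = GaussianMixtureField(R1=o.get("R1", 4.0), R2=o.get("R2", 1.0))
    lp = coefficients_from_mechanism(cfg.agent, cfg.circuit)
    box = tuple(o.get("box", (-90.0, 90.0)))
    edges = np.linspace(box[0], box[1], o.get("n_bins", 37))
    res = ensemble_langevin(
        lp,
        field,
        n_walkers=o.get("n_walkers", 200),
        T=o.get("T", 1000.0),
        dt=o.get("dt", 0.01),
        seed=int(rng.integers(2**31)),
        box=box,
        bin_edges=edges,
    )
    law = stationary_density(lp, field, domain=box)
    p_emp = res.histogram / res.histogram.sum()
    p_law = law.bin_probabilities(edges)
    l1 = float(np.abs(p_emp - p_law).sum())
    summary = {"beta": lp.beta, "l1_distance": l1}
    with open(out / "langevin_stationary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _exp_td_chain(cfg: RunConfig, rng, out: Path) -> dict:
    o = cfg.options
    params = TDParams(
        gamma_disc=o.get("gamma", 0.9),
        alpha_lr=o.get("alpha", 0.02),
        N=o.get("N", 5),
        episodes=o.get("episodes", 3000),
        reward_model=o.get("reward_model", "deterministic"),
        magnitude=o.get("magnitude", 50.0),
    )
    res = run_chain_experiment(params, seed=int(rng.integers(2**31)))
    res.to_frame().to_csv(out / "td_chain.csv", index=False, float_format="%.17g")
    return {
        "converged_log_v1": res.converged_log_v1,
        "analytic_target": res.analytic_target,
    }


def _exp_response_fit(cfg: RunConfig, rng, out: Path) -> dict:
    o = cfg.options
    if "input_csv" in o:
        from .calibrate import ResponseTable

        table = ResponseTable.from_csv(o["input_csv"])
    else:
        table = generate_synthetic_responses(
            a=o.get("a", 0.5),
            b=o.get("b", 1.5),
            mu=o.get("mu", 4.9),
            sub_const=o.get("sub_const", 3.2),
            noise_sd=o.get("noise_sd", 0.2),
            n_rep=o.get("n_rep", 1),
            seed=int(rng.integers(2**31)),
        )
    fit = fit_log_response(table)
    fit.to_json(out / "response_fit.json")
    return fit.to_dict()


_DISPATCH = {
    "circuit-step": _exp_circuit_step,
    "scale-invariance": _exp_scale_invariance,
    "s1-perturbations": _exp_s1_perturbations,
    "matching": _exp_matching,
    "langevin-stationary": _exp_langevin_stationary,
    "td-chain": _exp_td_chain,
    "response-fit": _exp_response_fit,
}


def run_experiment(config: RunConfig) -> dict:
    """Dispatch to the named experiment, write artifacts and a provenance JSON."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    result = _DISPATCH[config.experiment](config, rng, out)
    provenance = {
        "experiment": config.experiment,
        "seed": config.seed,
        "config_hash": config.digest(),
        "version": __version__,
        "numpy": np.__version__,
        "circuit": dataclasses.asdict(config.circuit),
        "agent": dataclasses.asdict(config.agent),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    if config.verbosity:
        print(f"[{config.experiment}] seed={config.seed} -> {out}")
    return result
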