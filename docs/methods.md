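# Methods

## The circuit model

Dopaminergic population activity `d` (spikes/s) is driven by the logarithm
of the expected-reward input `R` and inhibited by a GABAergic population `g`
that integrates dopamine's deviation from its homeostatic level `d0`:

    d' = ω_d (C + μ log R − α g − d)
    g' = ω (d/d0 − 1)

The integral feedback gives *exact adaptation*: the only fixed point is
`d = d0`, with `g* = α⁻¹(C − d0 + μ log R0)` tracking the log input.
Because `R` enters only through `log R`, relabeling `g → g + α⁻¹ μ log λ`
removes any constant factor `λ` from the input — the full output trajectory
depends on fold changes only (*fold-change detection*, FCD).  Expected
reward is the TD quantity `R = r + V(s′)` with `V` the discounted value
function; after adaptation to `V(s)`, a transition produces the logarithmic
prediction error readout `Δd = μ (log(r + V(s′)) − log V(s))`.

Four wirings are provided: `feedback` (default, above), `feedforward`
(expected reward drives `g` directly — also FCD), `quasi_static`
(the fast `d`-equation eliminated algebraically, `d = C + μ log R − αg`),
and `rectified`, which resolves the implicit relation
`d = (C + μ log R − αg)·d/(d + k_d)` as `d = max(0, C + μ log R − αg − k_d)`.
The rectified form keeps `d ≥ 0` on omission-like inputs; when `d` stays
positive it is *identical* to the quasi-static model (the `k_d` offset is
absorbed by the adapted `g`), which is the sense in which it reduces to the
FCD model for `k_d ≪ d0`.  The implicit relation admits more than one
reading; this closed-form resolution is the package's documented choice.
The feedback/feedforward variants may go negative on strong downward steps —
a known limitation of the log-linear model, retained deliberately.

### Parameters

| name | meaning | mouse | primate |
|------|---------|-------|---------|
| ω_d  | dopamine relaxation rate (1/s) | 50 | 100 |
| ω    | adaptation rate (1/s)          | 15 | 30  |
| C    | baseline drive (spikes/s)      | 15 | 15  |
| μ    | logarithmic gain (spikes/s)    | 6  | 6   |
| α    | inhibition strength (–)        | 0.7| 0.7 |
| d0   | adapted level (spikes/s)       | 5  | 5   |

The mouse and primate columns are the phasic-response estimates; mouse
values are the package defaults.  The navigation (matching) analysis uses
the mouse rates with gain μ = 4, the value quoted for that analysis.

### Numerics

For arbitrary signals the circuit is integrated with an adaptive RK45 solver
(`rtol=1e-10`, `atol=1e-12`) restarted at every listed input discontinuity,
so steps are exact jumps rather than smoothed ramps.  Inside the
run-and-tumble loop, where the input is piecewise-constant over one movement
step, the feedback/feedforward systems are linear in `(d, g)`, and the
update `u(t+Δt) = e^{AΔt} u + (e^{AΔt} − I)A⁻¹ c(log R)` with a precomputed
2×2 matrix exponential is exact and fast; the rectified variant (only
piecewise-linear) takes four RK4 substeps instead.  At discontinuity
instants, variants with algebraic `d` report the post-jump value while ODE
variants report the continuous state — traces differ at that single sample
by construction.

## Run-and-tumble reward-taxis

The agent moves at speed `v` along a heading that is redrawn uniformly
("tumble") as a per-step Bernoulli event of rate `1/τ` (optionally
correlated with the previous heading; in 1-D a tumble draws ±1 with equal
probability).  Dopamine modulates either speed, `v = v0 (d/d0)^h` clipped at
zero (default, `h = 1`), or the tumble rate, `τ⁻¹ d0/d`.  Circuit state is
carried continuously across tumbles.  Simulations run in a reflecting box
sized three times the peak separation (±90 cm for the two-peak field);
doubling the box does not change near-peak statistics.  The step `Δt` must
satisfy `Δt ≪ τ`; the navigation experiments use `Δt = 5–10 ms` with
`τ = 100 ms`, and halving `Δt` changes the recovered exponent by less than
its sampling error.

## Coarse-graining and the matching law

On long timescales the walk is described by the Langevin equation

    dx = χ ∇log R(x) dt + √(2D) dW,   D = v²τ/m,   χ = D·(hμ/d0)

whose stationary density is `P(x) ∝ R(x)^β` with `β = χ/D = hμ/d0`: the
generalized matching law `P(x1)/P(x2) = k (R1/R2)^β` with `k = 1` absent
multiplicative preference biases.  With the recorded mouse estimates
`μ ≈ 5`, `d0 ≈ 5` spikes/s, `β ≈ 1` — close to perfect matching.
`simulate_langevin` / `ensemble_langevin` use Euler–Maruyama with
seed-deterministic Gaussian increments; stationary statistics discard the
first 20–25% of each path (doubling the burn-in does not change results).
The first Gaussian of the two-peak field uses the same width `b` as the
second by default (an asymmetric-width option doubles the first width;
the choice does not affect matching).

### Validity regime of the coarse-graining

The drift formula is an asymptotic statement.  It requires runs long
compared with the dopamine response, short compared with adaptation, and a
circuit memory short compared with the field's length scale:

    1/ω_d ≪ τ ≪ t_a = d0/(αω),      v·t_a ≪ b.

Outside the first two separations the drift of the full two-ODE circuit is
attenuated: linear-response analysis of the speed-modulated walk in a
constant log-gradient gives

    drift = χ ∇log R · [ω_d/(ω_d + 1/τ)] · [1/(1 + αωτ/d0)]

(`langevin.run_and_tumble_attenuation`), and the package's simulations
confirm it — diffusivity matches `v²τ` to 1%, and the measured drift is
0.83·χ∇logR at a parameter point where the predicted product is 0.85.
When the third separation fails (adaptation so slow that the memory length
`v·t_a` exceeds the field scale), the drift becomes nonlocal, agents stall
when the remembered descent drives `d` to zero, and the exponent instead
*overshoots*.

For the two-peak navigation setup (`τ = 0.1 s`, `v = 10 cm/s`,
`b = 10 cm`), `b/v = 1 s`, so no adaptation rate satisfies
`0.1 s ≪ t_a ≪ 1 s` with room to spare; the asymptotic exponent
`β = μ/d0` is not exactly reachable by the explicit agent in this geometry.
Measured exponents (run-and-tumble, μ/d0 = 0.8): at the mouse rates
(`ω_d = 50`, `ω = 15`; `t_a = 0.48 s`) β̂ ≈ 0.55 — in quantitative
agreement with the attenuation product 0.69; at `ω_d = 500` with
`ω = 22.6` (t_a = 0.32 s) β̂ ≈ 0.61, with `ω = 5` (t_a = 1.4 s)
β̂ ≈ 0.76, and with `ω = 1.5` (t_a = 4.8 s, memory 48 cm — nonlocal)
β̂ ≈ 0.9–1.0.  Tumble-rate modulation behaves the same way (β̂ ≈ 0.6 at
mouse rates).  The package's navigation experiments run at the mouse rates,
report the attenuated exponent, and test it against the linear-response
prediction; the asymptotic value `β = μ/d0` is recovered exactly by the
coarse-grained Langevin simulation, where it enters by construction.

## Matching experiment protocol

Reward ratios `R1/R2 ∈ {1/8, 1/4, 1/2, 1, 2, 4, 8}` on the two-peak field
(peaks ±30 cm, width 10 cm), occupancy measured in ±2.5 cm windows, pooled
over replicate walkers (default ≥ 10 replicates of 1500–2000 s; the default
budget gives each ratio hundreds of window visits).  `β̂` and `k̂` come from
unweighted OLS of `log(T1/T2)` on `log(R1/R2)` with 95% CI from the
t-distribution; ratios with an empty window are dropped with a warning.
The acceptance harness uses 40 replicates × 2000 s (run-and-tumble) and
300 × 2000 s (Langevin) — sizes chosen so the slope standard error is well
below 0.1.

As a negative control, replacing `∇log R` by `∇R` in the drift (the
`drift="linear"` option) destroys the power law: local log-log slopes vary
by far more than 20% across the ratio grid, showing that logarithmic
sensing is what produces matching.

## TD learning with logarithmic values

The classic tabular rule `V(s) ← V(s) + α(r + γV(s′) − V(s))` has the
logarithmic counterpart

    log V(s) ← log V(s) + α (e^{δ_log} − 1),
    δ_log = log(r + γV(s′)) − log V(s),

whose expected update vanishes exactly at the classic fixed point
`V(s) = E[r + γV(s′)]` for any reward distribution, and which agrees with
the log of the classic update to first order in `δ_log`.  The chain
experiment walks `N = 5` states with learning rate `α = 0.02` and a reward
drawn at the final state (deterministic, truncated normal with CV 0.3, or
Bernoulli); the analytic convergence target is `log(γ^{N−1} E[r])`.  The
discount is configurable with default `γ = 0.9`, and convergence is always
checked against the analytic value.  Conventions: terminal value 0,
`log V` initialized at 0
(insensitive to initialization), and — because a strictly zero reward makes
the logarithmic target undefined — the unrewarded Bernoulli outcome pays a
small positive floor (10⁻³ of the magnitude), a genuine limitation of
purely logarithmic coding.  Multiplying all rewards by λ shifts every
converged `log V` by exactly `log λ` — the learning-side face of FCD.

## Dose–response calibration

`Δd = μ log(a·u + b)` (natural log; the base only rescales μ) is fit by
multi-start (5 jittered initializations) trust-region least squares, with a
single subtraction constant shared by cued rows when present, standard
errors from the Jacobian, and `r² = 1 − SS_res/SS_tot`.  The
three-parameter form is identifiable on ≥ 4 distinct magnitudes (the
scale degeneracy `(a,b,μ) → (ca,cb,μ)` requires a free intercept, which the
model does not have); the Gram matrix condition number on the default
design is ~10⁶, comfortably invertible.  No real recordings are bundled:
the synthetic generator defaults to the reference best-fit constants
(`a = 0.5`, `b = 1.5`, `μ = 4.9`, subtraction 3.2) on a seven-magnitude
volume ladder (0.1–20 µl, the package's choice of design), and recovery is
validated by Monte Carlo (bias < 5% at σ = 0.2 spikes/s noise).

## What the synthetic data do and do not show

All inputs are constructed: step and cue→reward signals, Gaussian-mixture
and exponential-decay fields, and noisy dose–response tables.  Passing
tests demonstrate internal consistency of the model chain — circuit →
movement → stationary behavior → matching exponent — and recoverability of
its parameters from data *generated by the model itself*.  They do not test
dopaminergic heterogeneity, learned (rather than given) spatial fields,
real measurement noise structure, or whether biological rewards obey the
logarithmic response outside the measured magnitude range.

## Known limitations

- The log-linear circuit goes negative on strong downward steps; use the
  rectified variant when non-negativity matters.
- The matching exponent equals `μ/d0` only inside the timescale hierarchy
  above; at the phasic-response rates the explicit agent genuinely
  undermatches (β̂ ≈ 0.55 rather than 0.8 in the standard two-peak setup),
  by the attenuation factor the package computes and verifies.
- Occupancy-ratio estimates are slow to converge (well-to-well crossings
  are rare events); budgets below the defaults give very wide CIs.
- The Bernoulli reward floor in the TD module is a modeling convention, not
  part of the learning rule.
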