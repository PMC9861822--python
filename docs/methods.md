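# Methods

## The equivalent circuit

A solvent-containing planar bilayer under voltage clamp is modelled as
three parallel branches driven by the command voltage `U(t)`:

1. **Viscoelastic branch** — a series resistance `r` (set by the solvent's
   viscosity) feeding a nonlinear capacitance
   `C₁(Ũ) = (1−κ)·C₀·(1 + β·Ũ²)`, where `Ũ` is the voltage across `C₁`.
   Physically `Ũ` tracks the electric displacement, which lags the field
   because solvent redistribution and electrostriction are slow. Only the
   combination `τ = (1−κ)·r·C₀` enters the solution; `r` is derived, never
   stored. State equation:

   `τ·(1 + β·Ũ²)·dŨ/dt + Ũ = U(t)`, with `i₁ = (1−κ)·C₀·(U − Ũ)/τ`.

2. **Elastic branch** — `i₂ = κ·C₀·dU/dt`. The fraction `κ` of the
   membrane responds instantaneously; its own capacitance nonlinearity is
   far weaker than the solvent-mediated one and is fixed at zero.

3. **Ionic branch** — `i₃ = g·U + γ·U⁹`. The ninth-order term is an
   empirical description of the steep conductance increase above
   ≈150 mV; it is a reported trend, not a mechanistic claim.

The drive is a symmetric triangle: amplitude `Umax`, frequency `f`, period
`T = 1/f`, sweep rate `k = 4·Umax·f`, phase convention `U(0) = −Umax` at
the foot of the up ramp. Internally everything is SI; JSON/CSV interfaces
use unit-suffixed keys (`C0_pF`, `tau_ms`, `g_nS`, `gamma_nS_per_mV8`,
`Umax_mV`). The γ unit conversion is the classic trap:
`0.5·10⁻¹⁸ nS/mV⁸ = 5·10⁻⁴ S/V⁸`.

## First-order perturbation solution

For `β·Umax² < 1` the state equation is expanded in `β`. On the up half
(`0 ≤ t ≤ T/2`), with the transient amplitude `A_up = 2kτ` fixed by
periodic matching of the zeroth-order solution,

```
Ũ_up = −Umax − kτ + kt + A_up·e^(−t/τ)
       − βkτ(Umax² + 4·Umax·kτ + 5(kτ)²)
       + 2βkτ(Umax + 2kτ)·kt − βkτ(kt)²
```

and the total current, written against voltage via `kt = U + Umax`,

```
I_up(U) = k·C₀(1 + β_exp(U² + 5(kτ)²)) + (g + γU⁸ − 4β_exp·k²C₀τ)·U
          − 2kC₀(1−κ)·e^(−(U+Umax)/(kτ))
```

with `β_exp = β(1−κ)`. The down half is the exact odd image of the up half
(all three branch currents are odd under `(U, Ũ) → (−U, −Ũ)`), so the
time-inverted down branch is `I_down_inv(U) = −I_up(−U)`, carrying its
transient at the apex. Key derived quantities:

* apparent capacitance at zero voltage `C_exp0 = C₀(1 + 5β_exp(kτ)²)`;
* insertion (zero-hysteresis) conductance `g* = 4·β_exp·k²·C₀·τ`;
* apparent conductance `g_app = g − g*` (the identity `g_app + g* = g` is
  exact by construction);
* loop width `C_up − C_down = (2/k)(g + γU⁸ − g*)·U` plus transient terms —
  each branch deviates by half the width from the common backbone;
* source work per period, net of reversal transients,
  `W = (T/3)·Umax²·g_app`.

**Transient conventions.** The textbook-style forms above truncate the
transient at zeroth order in `β` (`transients="printed"`, the default, and
what the estimation protocol inverts). The dropped O(β) transient pieces
decay only like `e^(−t/τ)`, so near a reversal they dominate the error
budget. `transients="full"` carries the complete first-order transient —
the corrected exponential amplitude plus the `t·e^(−t/τ)`, `e^(−2t/τ)` and
`e^(−3t/τ)` terms the perturbation hierarchy generates — and is the form
whose error against the exact ODE is O((β·Umax²)²) already beyond a 3τ
guard band. `transients="none"` gives the smooth loop backbone used for
regime classification and the energy integral.

**Energy bookkeeping.** `W = (T/3)Umax²·g_app` deliberately excludes the
reversal transients: they dissipate `(1−κ)k²C₀τ(T−4τ)` in the series
resistance every period *regardless of regime* (for the published
parameter sets this term is the same order as `W` itself), so the total
loop integral `∮I·U dt` is positive even when `W < 0`. What `W < 0` means
is that the smooth part of the cycle returns energy to the source — the
memcapacitance process is active. `work_integral(..., include_transients=True)`
computes the full integral and the package tests the decomposition against
the closed-form dissipation above. The exact-solver energy balance is
`∮U·I₀ dt = ∮U·i₃ dt + r∮i₁² dt` over a steady period (capacitors are
conservative over a cycle).

**Ferroelectric counter-example.** If the branch charge law is inverted —
`U = v + (β/3)v³` with `v = q/((1−κ)C₀)`, a ferroelectric-like saturating
capacitance — the same perturbation method gives
`I_up = kC₀(1 − β_exp(U² + 5(kτ)²)) + (g + γU⁸ + 4β_exp·k²C₀τ)U + …`:
capacitance *decreasing* with voltage, insertion conductance *positive*,
hysteresis sense reversed and never pinched. Both laws share their own ODE
oracle (`law="ferroelectric"`), against which the signs and the linear
coefficient are verified.

## Exact solver

The scalar state ODE is integrated half-period by half-period with LSODA
(the ramp corner makes `dU/dt` discontinuous at `t = nT/2`; restarting at
each reversal keeps the integrator's order). The periodic steady state is
a fixed point of the period map on `Ũ` at the ramp foot, detected to the
absolute tolerance (default 10⁻¹² V; relative 10⁻⁹). Starting from the
linear-lag value `−Umax + kτ`, convergence takes ≤3 periods when
`T ≥ 20τ`. The returned steady period keeps the apex sample twice — once
per slope — because the elastic current jumps by `2κkC₀` there and each
half-cycle branch needs its own one-sided value. `τ = 0` short-circuits to
the algebraic solution `Ũ = U`.

## Instrument model

The clamp amplifier's feedback loop low-passes the recorded current:
`dU_out/dt + U_out/τ_out = I₀·R_out/τ_out`, `τ_out = R_out·C_out`
(typical 0.8 ms at 100 MΩ). For the linear membrane the output after an
up-ramp reversal is

```
U_out/R_out = kC₀ − [2(1−κ)kC₀/(1 − τ_out/τ)](e^(−t/τ) − e^(−t/τ_out))
              − 2kC₀·e^(−t/τ_out)
```

starting at `−kC₀` (continuity with the settled previous half) and
settling to `+kC₀`; for `τ_out ≪ τ` this is the two-exponential form with
amplitudes `2(1−κ)kC₀` (membrane) and `2κkC₀` (instrument) — the route by
which `κ` is read off real recordings. Note the lag inflates the fitted
slow amplitude by `1/(1 − τ_out/τ)` (≈4% at 0.8 ms/21 ms); the
decomposition tests undo it with the known instrument constant. The
discrete filter uses the exact zero-order-hold update
`y[n+1] = a·y[n] + (1−a)·x[n]`, `a = e^(−1/(fs·τ_out))` — forward Euler is
badly wrong when `τ_out` is comparable to the sample interval.

## Synthetic recordings

`generate_trace` plays the exact ODE forward from a cold start — the
membrane equilibrated at the ramp foot, `Ũ(0) = −Umax` — so the first
cycles carry a genuine startup transient, as in a real recording; the
estimation pipeline discards them. Defaults mirror the published recording
protocol: 1 kHz sampling, 25 periods, amplitudes 50–300 mV, frequencies
0.01–2 Hz. Noise is additive white Gaussian on the current, default
SD 5 pA — the simplest model consistent with the reported need to average
over 30 ms, and the visible fluctuation scale for nF membranes; no
published noise amplitude exists, so it is a free parameter. The generator
does **not** emulate 1/f noise, mains pickup, amplifier clipping at high
currents, or membrane rupture — parameter-recovery results on synthetic
data therefore demonstrate correctness of the pipeline's inversion, not
robustness to every artifact of real recordings.

Built-in reference sets: `azolectin_200mV_1Hz` (C₀ = 897 pF,
β_exp = 11 V⁻² ⇒ intrinsic β = 13.75 V⁻² at κ = 0.2, τ = 19 ms,
g = 0.05 nS, γ = 5·10⁻⁴ S/V⁸) and the `regime_{negative,zero,positive}_gapp`
family (C₀ = 1120 pF, τ = 10 ms, β_exp = 15 V⁻², 200 mV / 2 Hz,
g = 0, 1.72, 8 nS). The regime family's quoted nonlinearity is interpreted
as *effective* (`β_exp`), because `4·15·k²·C₀·τ` reproduces the quoted
1.72 nS zero-hysteresis conductance exactly while the intrinsic reading
would not; κ is set to 0.2 as for the azolectin membrane.

## Paired-ramp estimation

Pipeline on one record (`estimate_parameters`):

1. **Segment & fold.** Realign to the drive phase by circular
   cross-correlation of the period-averaged voltage channel (or, without
   one, the current against the capacitive square-wave pattern, snapped to
   the `+2κkC₀` jump at the up reversal); drop the first 2 cycles;
   average the rest; map up samples to `U = −Umax + kt` and time-inverted
   down samples likewise; average into 2 mV voltage bins. A 30 ms centered
   moving average (edge-truncated) smooths the binned curves only — the
   time-domain segments kept for transient fitting are never smoothed.
2. **Decompose.** `half_diff = (I_up − I_down_inv)/2` (capacitive, even)
   and `half_sum = (I_up + I_down_inv)/2` (conductive, odd).
3. **Capacitance fit.** Parabola `half_diff/k = C_exp0(1 + b·U²)` on
   `|U| ≤ 0.6·Umax`, additionally excluding a guard band of width
   `3kτ̂ + k·(smoothing window)/2` at each ramp end — the reversal
   exponentials enter the half-difference as a spurious *even* term and
   bias the curvature downward on fast drives if left in.
4. **Conductance fit.** Slope through the origin of `half_sum` on
   `|U| ≤ 0.5·Umax` (same guard), below the region where `γU⁹` bends the
   curve. This is `ĝ_app`; only the apparent conductance is identifiable
   from the curves alone.
5. **Transient fit.** Single exponential over a quadratic baseline on the
   *half-difference versus time* near the ramp start (window ≈4 fitted
   time constants; the ionic terms, including the steep `γU⁹`, cancel
   identically there; the quadratic baseline captures the `β_exp·U²` term
   exactly since `U` is linear in `t`). Because the exact relaxation at a
   reversal is governed by the quasi-steady lag of the nonlinear branch,
   `U − Ũ = kτ(1 + βŨ²)`, the fitted amplitude and decay constant are both
   inflated by `(1 + β·Umax²)`; the pipeline inverts
   `A = kC₀(1−κ)(1+βUmax²)`, `τ_fit = τ(1+βUmax²)` self-consistently with
   `β = β_exp/(1−κ)`. With an amplifier model, a two-exponential fit on
   the raw up segment is used instead and `κ̂ = a_fast/2`.
6. **τ refinement.** Bounded scalar minimization of the half-difference
   shape mismatch against the exact ODE solution (time-domain, unsmoothed
   — binning and smoothing smear the transient, which is exactly where the
   τ information lives). A first-order-analytic comparison mode exists but
   is reliable only for `β·Umax² ≪ 1`; at the azolectin nonlinearity it
   overshoots τ by ~2×, which is why the exact model is the default.
7. **Assemble.** `C₀ = C_exp0/(1 + 5β_exp(kτ̂)²)`,
   `ĝ = ĝ_app + 4β_exp·k²·C₀·τ̂`; `γ̂` as a trend from the high-voltage
   (`|U| > 0.75·Umax`) residual of the half-sum.
8. **Bias correction** (default on). The first-order protocol applied to
   the exact dynamics has a smooth O((β·Umax²)²) bias (at
   `β_exp·Umax² = 0.44` the raw `β̂_exp` is ~8% low). One parametric-
   bootstrap step measures it: simulate a noiseless recording from the
   point estimate, re-run the pipeline, subtract the observed self-bias
   from `C_exp0`, `β_exp` and `g_app`, and re-assemble. The transient-
   derived `κ̂`, `τ̂` are left at their direct values; their error map is
   not locally linear and the one-step correction degrades them.

### Accuracy and limits

On noiseless 25-period synthetic records with `k·τ ≪ Umax` and
`T ≥ 20τ`, the pipeline recovers `C₀` and `β_exp` to well under 1%, `τ`
within a few percent, `κ` within ±0.02 and `g` within ±0.05 nS (tested at
`β_exp` up to 20). Recovery degrades when (a) the transient footprint
`kτ` approaches a substantial fraction of `Umax` (at 2 Hz with τ = 12 ms
the transients plus the 30 ms smoothing smear occupy ≈30% of the sweep and
bias the curvature fit by ~10% even with guard bands), or (b) the
smoothing window is not small against the half period (keep
`T/2 ≥ 10 ×` window; the defaults violate this above ≈1.5 Hz, where
smoothing should be reduced). Noise enters the folded curves at
`σ/√(n_cycles·samples-per-bin)` and is negligible at 5 pA / 23 cycles next
to the systematic terms above.

## Numerical choices

* Solver LSODA, rel 10⁻⁹ / abs 10⁻¹² V, restart at reversals; steady state
  by period-map fixed point, not energy criteria (simpler and sufficient
  for a scalar state).
* Closed-form operations warn (`ValidityWarning`), not fail, when
  `T/2 < 5τ`, where the transient-decayed assumption degrades.
* Curve fits run on quantities scaled to O(1) (currents in units of
  `k·C₀`) where bounded least squares is involved; `τ = 0` and `κ = 1`
  short-circuit to the degenerate algebraic forms everywhere rather than
  dividing by zero.
* All randomness flows through a single integer seed
  (`numpy.random.default_rng`); noiseless runs are bit-reproducible.

## Known limitations

* Triangular drive only; no sinusoidal or arbitrary waveforms, and no
  access/series solution resistance.
* First order in `β` throughout the closed forms; at `β·Umax² ≳ 0.5`
  expect mid-range deviations of several percent from the exact response
  (the bias-corrected estimator compensates for this in recovery, the
  forward formulas do not).
* `γ̂` is a trend indicator only — the high-voltage conductance rise is
  not mechanistically modelled, and real recordings clip there.
* No frequency-dependent `β(f)`, `τ(f)` model: a frequency sweep yields
  independent per-frequency estimates (`memblm sweep`), nothing more.
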