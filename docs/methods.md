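# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations behind `fermlogic`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Sensor models

Each sensor promoter is a four-parameter Hill response.  For an
activating sensor (glucose, acetate),

    y(s) = y_min + (y_max − y_min) · sⁿ / (EC₅₀ⁿ + sⁿ),

and for the depletion-activated low-oxygen sensor the fraction is
`EC₅₀ⁿ / (EC₅₀ⁿ + sⁿ)`, so output rises as dissolved oxygen falls.  In
both modes `y(EC₅₀)` is exactly the midpoint of `[y_min, y_max]`.

Defaults carry the measured characteristics of the three sensors:
half-max at 0.1 % glucose (g/g), 36 µmol/l DO and 13.8 mM acetate, with
dynamic ranges 18-, 25- and 250-fold.  Two deliberate choices:

- **Hill slope n = 1.**  No slope was reported for any sensor; n = 1 is
  the least-committal saturating choice and is always re-fittable.
  Note an internal tension this creates for the oxygen sensor: with
  n = 1 and EC₅₀ = 36 µmol/l, the ratio of outputs between DO = 0 and
  air saturation (210 µmol/l) can be at most ≈6.8, so the 25-fold
  dynamic range is necessarily an asymptotic (model) quantity, not an
  observable on/off ratio within the physical DO range.  This drives
  the identifiability limits discussed under *Fitting* below.
- **Normalisation.**  `y_max = 1` and `y_min = 1/fold` in arbitrary
  units; when calibrated RPU output is needed the normalised response is
  mapped linearly onto the sensor's measured RPU range (glucose
  0.006–0.237, low-oxygen 0.020–1.346, acetate 0.002–0.700).  The
  fluorescence→RPU conversion is a single global factor (10⁻³),
  overridable per calibration object; whether it should differ per
  sensor is not established.
- Population-median behaviour only: the acetate sensor's bimodal
  response at intermediate doses is not modelled.

## Fitting dose–responses

`fit_hill` minimises least squares on **log-responses**.  The package's
synthetic fluorescence data (and real cytometry medians) carry
multiplicative, roughly constant-CV noise, for which log-space least
squares is the maximum-likelihood estimator; linear-space residuals let
the on-state dominate and leave the off state (hence the dynamic range)
effectively unconstrained.  y_min, y_max and EC₅₀ are always free with
positivity bounds; the slope is free by default and can be pinned via
`hill_n=` when it is known.  Initialisation: y_min = min(data),
y_max = max(data), EC₅₀ = dose nearest the midpoint response, n = 1.
Convergence failure and log-scale R² below 0.5 (e.g. monotone-decreasing
data under an activating model, which the optimizer can only fit by
inverting y_min/y_max) raise the `poor_fit` flag; nothing is silently
replaced.

**Recovery experiments** (tests and the acceptance script) characterise
each sensor with 12 doses × 3 replicates at 5 % CV — the reference
experiment size — and pin the slope at the generating n = 1, since the
slope is part of the declared simulation conditions.  Expected scatter
at this size, from the Fisher information of the log-space model
(verified by Monte-Carlo over hundreds of seeds):

- half-max points: ~3–7 % relative sd (all three sensors);
- dynamic range: ~3 % sd for glucose and acetate (their off states are
  measured directly at zero dose);
- dynamic range of the oxygen sensor: ~13 % sd.  Its off state lies
  beyond the physically reachable dose range (210 µmol/l ≈ 5.8×EC₅₀
  reaches only within ~15 % of range of y_min), so the fold is an
  extrapolated quantity; the estimator is unbiased (Monte-Carlo median
  24.8 vs 25) but individual noise realisations can miss a 15 % band —
  roughly four seeds in ten do.  The oxygen dose panel therefore weights
  levels near air saturation; no 12-level panel does materially better.

## Gate response functions

- NOT/NOR (repressor): `y = y_min + (y_max − y_min)·Kⁿ/(Kⁿ + xⁿ)`, with
  `x` the *sum* of input promoter activities for NOR.  Per-repressor
  constants belong to the user's parameter files; the shipped default
  (y_min 0.01, y_max 1.0, K 0.1, n 2, RPU) is a neutral mid-range
  repressor and claims no correspondence to any published gate.
- AND (SicA/InvF): `y = y_min + (y_max − y_min)·x₁x₂²/(K + x₁x₂²)` with
  measured constants y_min 0.001, y_max 0.3, K 10⁻⁵ (RPU³).  The squared
  x₂ is used exactly as characterised, not generalised.
- ANDN (PhlF): `y = y_min + (x₁ − y_min)·K/(K + x₂)`, constants
  y_min 0.001, K 0.0025.  For x₁ < y_min the formula would undershoot
  its own floor; the response is clamped at y_min.  The genetic
  implementation reuses the glucose promoter for x₁; the model treats
  both as the same wire value.

## Digitization and enumeration

Truth tables are read off a circuit by evaluating the analog steady
state at every input corner (each sensor at its RPU minimum or maximum)
and thresholding each output at the **geometric mean of its own corner
extremes** — scale-free and symmetric in log space.  An output whose
extremes differ by less than a factor of 3 is flagged constant and
assigned its bit by comparison to the geometric mean of the producing
gate's floor and ceiling.

Two facts about digitization worth knowing:

- With its published constants the AND gate is too sensitive to be
  digital at the sensor corners: K = 10⁻⁵ RPU³ saturates even at the
  glucose *minimum* (0.006·0.7² ≈ 3·10⁻³ ≫ K), so the digitized
  single-AND table is not A∧B.  Logic-equivalence checks therefore use
  a *separating* parameter assignment (below).  The ANDN gate's
  published constants do separate cleanly.
- Because every response family here is soft (the AND form is
  first-order in its statistic; ANDN only attenuates by K/(K+x₂)), no
  single global parameter set digitizes all layered circuits correctly.
  `idealize_params` instead propagates the corner values and Boolean
  bits through the netlist and places each gate's K relative to what
  actually reaches it: repressors get K at the geometric mean of the
  largest ON-corner and smallest OFF-corner input with a steep slope
  (n = 4); AND gates get K at the weakest ON-corner statistic; ANDN
  gates get K at a third of the largest pass-corner x₂ (strong blocking
  at the cost of pass amplitude); Boolean-constant gates get K pushed
  far out so the output pins to floor or ceiling.  Under this
  assignment the digitized table equals the Boolean composition for
  every layered wiring at depth ≤ 2 (asserted exhaustively, ~1100
  wirings).

Enumeration builds layered expression trees over the three sensor wires
(gates never take the same wire twice — a gate wired against itself is a
physical contradiction whose fuzzy response has no consistent digital
reading), deduplicates by truth table, and is guarded against
combinatorial explosion (depth ≤ 3; the full four-kind alphabet at
depth 3 refuses with a count estimate).  At depth ≤ 2 the four kinds
reach 117 of the 256 possible 3-input tables.

## Circuit dynamics

Each gate integrates
`dy/dt = α·f(x(t)) − γ·(y − y_min)` where `f` is the x-dependent part of
its static response, so with α = γ the fixed point is exactly the static
composition.  α = γ = 1/h (gate on/off rates on the dilution
timescale).  The same production/relaxation structure extends the
repressor-gate ODE to the AND/ANDN forms.  Sensor inputs are piecewise
linear in time with terminal values held beyond the sampled range
(inventing trends beyond the data seemed worse).

Integration is fixed-step explicit Euler at dt = 0.025 h over 27 h — the
discrete solution the circuit models were characterised with — and a
classic RK4 stepper exists to verify adequacy: on all fixture circuits
driven by batch-derived inputs the two agree within 1 % sup-norm, and
halving dt moves the Euler solution by less than the previous halving
(first-order convergence).  The steady-state initial condition is
solved in closed form by topological substitution
(`y* = y_min + (α/γ)·f(x₀)`).  By default x₀ is the sensor time courses
interpolated at t_start; a fixed map can be supplied instead (the
worked three-repressor example uses the reference initial activities
x₁ = 1.294, x₂ = 0.006, x₃ = 0.028 RPU, kept verbatim as
`REFERENCE_INIT_SENSOR_RPU`; note the x₁ value exceeds the glucose sensor
maximum — the original sensor-to-wire assignment at t = 0 is ambiguous
and is left to the user).  Negative transients (impossible under the
shipped parameters, possible under user parameter files) are clamped at
zero with a warning; NaNs abort with the step and gate named.

## Promoter library design

Backbones are 150 bp: a 25 bp upstream spacer (−60..−35), a 35 bp σ70
core (−35..−1; −35 hexamer at local offset 0, −10 at offset 23), and a
90 bp downstream spacer.  The four bundled cores are **synthetic**
σ70-consensus-style sequences, screened to be free of duplicated
6-mers, BsaI sites and stray near-consensus hexamers — they are
stand-ins, not the registry sequences of the named promoters the
original library used (those are not reproduced here; real cores can be
supplied through the design spec.  Beware that some registry promoters
carry internal cloning-scar repeats, e.g. GCTAGC twice, and then fail
the default repeat screen unless `min_repeat_len` is raised).  Each of
the 12 backbones (4 cores × 3 spacer sets) gets its own random spacers,
drawn incrementally so the assembled backbone passes every screen;
member-level filter failures then come only from operator insertion.

Insertion geometry: singles are placed at every feasible position
(replace mode, preserving the 150 bp length; insert mode available).
Pairs are placed at three named sites — the +1 site, the −10/−35
spacer, and immediately upstream of the −35 — with a nominal 6 bp
inter-operator gap varied by ±6 bp and the pair anchor shifted ±6 bp.
Pairs that do not fit (notably all CRP-containing pairs upstream of the
−35, where only 25 bp exist) are skipped and counted.  The screen
rejects: any 6-mer occurring twice (the strictest common reading of a
">5 bp repeat" synthesis screen; configurable), BsaI GGTCTC/GAGACC on
either strand, and any ≤1-mismatch TTGACA followed 15–19 bp later by a
≤1-mismatch TATAAT outside the intended core coordinates (the intended
−35/−10 pair is whitelisted by position).  Finalised oligos are
tail + design + tail (190 bp); the 20 bp tails are the primer-annealing
ends of the amplification primers, and junctions are re-checked for
BsaI.  The default build yields 12,137 unique members from 29,220
candidates (seed 7) — the same order of magnitude as the original
11,964-member library; the exact count is seed-dependent through the
random spacers.

## Knockdown kinetics

Linear two-stage expression with mechanism switches at the induction
time t₀ (default 2 h):

    dm/dt = k_m·(1 − block·I(t)) − (d_m + s·I(t))·m
    dp/dt = k_p·m − (d_p + π·I(t))·p

Defaults: d_m = 3/h (≈14 min mRNA half-life), d_p = 1/h (dilution at a
1/h growth rate, consistent with the circuit model's α = γ = 1/h);
synthesis rates cancel from all normalised quantities.  Linear
(non-saturating) kinetics are a deliberate choice — no enzyme
saturation data exist to constrain more — and give the closed-form
steady-state fold `1/(1−block)·(d_m+s)/d_m·(d_p+π)/d_p`, from which any
measured fold calibrates its mechanism rate by inversion (69-fold →
block = 68/69; 10-fold → s = 9·d_m).  Consequences worth flagging:
folds multiply across mechanisms, so CRISPRi+protease predicts a larger
fold than CRISPRi alone, whereas the reference experiments could not
detect added potency (only added speed).  This divergence is kept
visible as a model property, not reconciled.  A time-varying dilution
hook `d_p_of_t` exists for stationary-phase slowdown; default constant.
Fold estimation from populations is the ratio of medians (the cytometry
statistic) with a seeded percentile bootstrap (1,000 resamples).

## Synthetic batch model

Monod growth `dX/dt = µ_max·G/(K_s+G)·X` with stoichiometric glucose
consumption `dG/dt = −µX/Y_xs`; dissolved oxygen relaxes quickly
(5/h) toward a quasi-static target
`DO_sat − c·(µ + m)·X` clipped at the 20 µmol/l probe floor — the
maintenance term m keeps DO depleted in stationary phase, as observed
in dense cultures; acetate is produced in proportion to biomass while
glucose remains above a detection level (overflow metabolism reduced to
its phenomenology: no acetate consumption phase, no mechanistic flux
model).  Defaults (X₀ = 0.01 OD, µ_max = 0.47/h, K_s = 0.05 %,
Y_xs = 5 OD/%, glucose₀ = 1.6 %, q_ac = 1.24 mM/OD/h, c = 950,
m = 0.05/h, DO_sat = 210 µmol/l) are calibrated once to the reference
fermentation landmarks and pinned: glucose spent at 15.0 h, DO below
36 µmol/l at 8.1 h, acetate past 15 mM at 13.9 h (each within the ±1 h
contract).  Only these three crossing times are calibrated; curve
shapes between them are the model's own.

What the generator does *not* emulate: measurement noise on the batch
trajectories, pH dynamics, nitrogen limitation, single-cell
heterogeneity, growth-rate feedback on gate parameters, and the slower
growth of circuit-bearing strains.  Tests passing on this generator
show that the estimators and models are mutually consistent at
realistic noise levels and experiment sizes — not that they would
survive every artefact of real fermentation data.

## Problem sizes and seeds

All stochastic components take explicit seeds; the test suite and
acceptance script derive theirs deterministically.  Sizes were chosen to
mirror the reference experiments' scales: 12 × 3 dose–responses, 10⁴-cell
populations, 27 h × 0.025 h simulations, the full default library
(~2.9 × 10⁴ raw candidates), and exhaustive depth-≤2 circuit
enumeration (~1100 wirings).

## Known limitations

- The oxygen sensor's dynamic range is an extrapolated quantity (see
  *Fitting*); treat recovered oxygen folds as ±15 % at best at this
  experiment size.
- NOR/NOT gate constants are placeholders pending user parameter files;
  digitization of circuits built on them reflects those placeholders.
- The enumeration treats circuits as expression trees (fan-out of
  intermediate gates is not explored); for truth-table coverage at
  depth ≤ 2 this loses nothing, but it does not enumerate every
  physical wiring.
- `estimate_fold` assumes unimodal populations; bimodal responses (the
  acetate sensor at intermediate doses) would need mixture handling.
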