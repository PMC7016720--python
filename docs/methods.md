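# Methods

## The gating model

`thermogate` implements an eight-state allosteric model of TRPA1 gating.
The channel is factorized into three two-state modules: the pore gate
(closed/open), a voltage sensor (resting/active) and a temperature sensor
(resting/active). Module equilibria are

- gate: intrinsic equilibrium constant `L`;
- voltage sensor: `K(V) = K0·exp(zFV/RT)`, with `K0` the equilibrium
  constant at 0 mV and `z` the apparent gating charge (elementary charges);
- temperature sensor: `J(T) = exp[−(ΔH° − TΔS°)/RT]`, with ΔH°, ΔS° the
  activation enthalpy and entropy in kcal·mol⁻¹(·K⁻¹).

Sensors bias the gate (and each other) multiplicatively through allosteric
coupling factors: `D` (voltage sensor ↔ gate), `E` (voltage ↔ temperature
sensor) and a temperature-dependent `C(T) = exp[−(ΔH°c − TΔS°c)/RT]`
(temperature sensor ↔ gate). A factor below 1 is an unfavorable
("inverted") coupling: an *activated* sensor then *disfavors* opening,
which is the mechanism by which a heat-activated sensor can produce cold
activation. The eight statistical weights are products of whichever
constants are "on" in a state, and

```
P_o = L(1 + KD + JC + JKCDE) / [(1 + K + J + JKE) + L(1 + KD + JC + JKCDE)].
```

All weights are evaluated in log space (log-sum-exp): with ΔH° = 91
kcal·mol⁻¹ the Boltzmann exponents exceed float range well inside the
5–60 °C operating window, and P_o must saturate to 0/1 rather than
overflow.

Sign convention: `z > 0` means depolarization-activated. Fitted parameter
sets reported with the opposite exponent convention (negative z for a
channel whose conductance grows with depolarization) are normalized on
load and flagged, never silently rewritten.

A consequence worth stating explicitly: P_o is *not* monotone in voltage
for all parameter sets. The open-probability odds are a ratio of two
polynomials linear in K, so the odds change across a voltage interval is
bounded by the Boltzmann factor `exp(|z|FΔV/RT)`, and its *sign* depends
on the couplings; with `D < 1` depolarization can close the channel. The
cold-sensitized regime (below) lives in exactly this inverted-voltage
region.

## Kinetic realization

The equilibrium landscape is the constrained object; rate constants are a
package choice. Each of the twelve cube edges is assigned
`k_forward = k_ref·Keq^φ`, `k_backward = k_ref·Keq^(φ−1)` with the edge's
full equilibrium constant (allosteric factors included) taken from the
state weights, one reference rate per transition class (gate, voltage
sensor, temperature sensor) and a single split exponent φ ∈ [0, 1]
(default 0.5). Because both rates of every edge derive from the same state
free energies, every closed cycle satisfies detailed balance by
construction and the stationary distribution of the generator equals the
equilibrium weights exactly.

A power-law rate model diverges on strongly biased edges (the faster rate
grows like `exp(|ΔG|/2)`), which is both unphysical and numerically
destructive. The faster rate of each edge is therefore capped (default
`k_max` = 1e8 s⁻¹; the orthologue presets use 1.5e3 s⁻¹, emulating rate
saturation of conformational transitions) by shifting both log-rates
equally, which leaves the edge's equilibrium ratio — and hence detailed
balance — exact and only slows that edge's relaxation.

Propagation uses the matrix exponential of the generator per sample
interval: exact on piecewise-constant (V, T) segments; temperature ramps
are discretized at the sample interval with the midpoint temperature
(second-order accurate; halving dt at 0.25 ms moves ramp endpoints by
< 1e-6). Propagators are cached per (regime, V, T, dt), so step protocols
cost one `expm` per segment. Each step's output is projected back onto the
probability simplex to absorb float drift; drift beyond 1e-6 raises
instead of being normalized away.

Default reference rates (overridable): k_gate 100 s⁻¹, k_vsensor and
k_tsensor 400 s⁻¹, placing voltage-step relaxations in the
tens-of-milliseconds range of whole-cell TRPA1 recordings. The presets
(below) use tuned values.

## The blue/green/red regimes

The hTRPA1 activation profile is modeled as three parameter sets sharing
one topology, with latched transitions between them:

- **blue** — the naive channel;
- **green** — after exposure to heat above 60 °C (the irreversible switch
  that blunts subsequent depolarization responses);
- **red** — after *concurrent* depolarization and noxious heat (the
  cold-sensitized, inwardly rectifying state).

Published constants: K0 = 0.003, |z| = 0.74, ΔH° = 91 kcal·mol⁻¹,
ΔS° = 0.317 kcal·mol⁻¹·K⁻¹ (temperature-sensor values adopted from TRPM8),
blue ΔH°c = 6.1 kcal·mol⁻¹. The remaining blue constants (L, D, E, ΔS°c)
are not published; they were calibrated once against the published 25 °C
Boltzmann parameters (V50 = 66.5 mV, z = 0.76, Gmin/Gmax = 0.8/23.5 nS),
the 2.3%-of-maximum basal conductance at (−150 mV, 25 °C), a small cold
basal at −70 mV, and a mild interior-minimum (U-shaped) P_o–temperature
relation at +80 mV, then frozen:

```
L = 0.00398, D = 61059, E = 0.0311, ΔS°c = 0.02386 kcal·mol⁻¹·K⁻¹
```

This blue landscape has V50(25 °C) ≈ 72 mV shifting down on warming,
basal fraction 0.023 at (−150 mV, 25 °C), P_o(−70 mV, 5 °C) ≈ 0.08 and its
U-minimum near 22 °C. V50 cannot be driven all the way to the printed
66.5 mV once the cold-basal and coupling-ordering constraints are also
honored — the printed |z| = 0.74 bounds how much voltage dependence the
model can express — and the landscape is therefore constraint-consistent
rather than a reproduction.

### Constrained sequential refits

Green and red are *refits* of blue against published open-probability pins
(four per stage, e.g. green P_o = 0.15 at (−70 mV, 60 °C), red P_o = 0.998
at (−70 mV, 5 °C)):

- green: {L, E, D, ΔH°c, ΔS°c} free; K0, z, ΔH°, ΔS° frozen at blue;
- red: two sequential steps — first {D, L, ΔH°c, ΔS°c} free with E and ΔS°
  held at green, then {E, ΔS°, ΔH°c, ΔS°c} free with D and L held at the
  step-1 solution.

The solver is seeded differential evolution (population initialized around
the incoming parameter set) plus a deterministic Nelder–Mead descent from
that set; the best objective wins across three restarts. The pin penalty
uses the fourth power of the relative residuals (near-minimax — the
scientifically meaningful number is the worst pin), and a weak (1e-7)
log-space proximity regularization toward the preceding stage selects the
minimal-perturbation solution when the pins alone are degenerate. This
mirrors the sequential-constraint rationale under which such fits converge
to similar solutions from different starting points, and in practice makes
repeated seeded fits land on the same landscape to ~1e-7 in P_o.

Two structural facts about the red pins deserve record. First, the two
5 °C pins (0.998 at −70 mV, 0.23 at +80 mV) demand an open-probability
odds ratio of ~1670 across 150 mV, while a |z| = 0.74 voltage sensor
bounds that ratio by exp(0.74·F·150 mV/RT) ≈ 103 at 5 °C; the pins are
therefore not exactly satisfiable by *any* parameter set with the frozen
z, and the fitted optimum carries an ~8.5% worst-pin residual
intrinsically. Second, the red solution necessarily has D far below 1 and
a large E — voltage-sensor activation *suppresses* opening (inverted
coupling), which is what makes the refit direction checks (L and E up,
D down from green; E up and L down from blue to green) structural rather
than accidental.

### Regime switching in time

`simulate_with_regimes` latches parameter-set switches on stimulus
conditions: by default green latches once the trace temperature exceeds
60 °C, red once V ≥ +80 mV and T ≥ 60 °C hold concurrently for ≥ 0.5 s
(both thresholds configurable, and rules form an escalation chain — a
later regime can only latch after the earlier ones). The occupancy vector
is carried across each switch unchanged; only the generator changes. The
transient P_o excursions around heat episodes fall out of this: heating
drives P_o up along the old landscape, the latch drops the equilibrium,
and the trace decays toward it.

## Estimation toolbox

- **Boltzmann G–V**: bounded least squares (trust-region) of
  `G = (Gmax−Gmin)/(1+exp(−zF(V−V50)/RT)) + Gmin` with Gmin ≥ 0; flat
  curves are flagged unidentifiable instead of returning an arbitrary V50.
- **Relaxations**: mono/bi-exponential fits with the first 1.3 ms after
  the step excluded (clamp settling). A two-component request falls back
  to one component when τ ratio < 3 or the minor amplitude < 5% — the
  printed fits chose "single or double" without a stated rule, so the
  rule is made explicit here. The amplitude-weighted
  τ_w = (A_f τ_f + A_s τ_s)/(A_f + A_s) is reported for comparisons.
- **Arrhenius/Q10**: OLS of ln(rate) on 1/T, Ea = −slope·R in kJ·mol⁻¹;
  Q10 = exp[(Ea/R)(1/T1 − 1/T2)] over a 10 °C window centered on the
  midpoint of the 10–35 °C characterization range (290.65–300.65 K). This
  window convention reproduces all six published (Ea, Q10) pairs after
  one-decimal rounding and is the package default.
- **Steady-state extrapolation**: exponential asymptote of rising,
  non-saturated activation traces (used at cold temperatures where 400-ms
  steps do not reach steady state); decaying traces are rejected and
  near-flat traces are flagged uncertain.

## Synthetic recordings

The generator composes gating (master equation), ohmic conduction
(`I = N·g·P_o·(V − Vrev)`) and additive Gaussian noise shaped by a
single-pole low-pass filter. Defaults: N = 5000 channels × 0.1 nS (≈ 23 nS
maximal whole-cell conductance scale at saturating P_o), Vrev = 0 mV
(symmetric monovalent solutions), 5 pA noise before filtering, 10 kHz
sampling, 2 kHz cutoff. Stimulation protocols mirror the study designs:
400-ms voltage steps −150→+100 mV with a −150 mV tail (11 sweeps, holding
0 mV), 100-ms steps −80→+200 mV (15 sweeps, holding −70 mV), 3-s
temperature staircases ~11→52 °C at +80 mV, 25→60 °C ramps at 35 °C/s, and
the interleaved depolarization/heat protocol with either stimulus order.

Orthologue presets differ only where the data constrain them: mTRPA1 is
hTRPA1 with a 6× larger L (≈ 12% vs 2.3% basal fraction at −150 mV, 25 °C)
and fast sensors (mono-exponential ~11 ms tail); hTRPA1 has a slow voltage
sensor so its −150 mV tail resolves two components (~2.6/16 ms) that the
fallback rule accepts as bi-exponential; the S804N-like mutant slows the
gate ~5× further on a 12× L (deactivation > 200 ms). The printed tail
decompositions (5.0/28.4 ms at 70/30% for hTRPA1, 9.1 ms for mTRPA1) are
matched in structure and order of magnitude, not digit-by-digit — three
reference rates cannot pin four independent time constants, and no rate
constants are published.

What the generator does *not* emulate: series-resistance and capacitance
transients, seal leak (optionally injectable as a constant conductance),
1/f noise, Ca²⁺-dependent potentiation/inactivation, and absolute current
amplitudes (channel counts are not published). Tests passing on this
generator therefore validate the estimators against the model's own
statistical structure, not against instrument artifacts.

## Numerical choices

- Physical constants: R = 1.98720×10⁻³ kcal·mol⁻¹·K⁻¹ (model units),
  8.31446×10⁻³ kJ·mol⁻¹·K⁻¹ (Arrhenius units), F = 96485.332 C·mol⁻¹;
  1 kcal = 4.184 kJ. Temperatures Kelvin internally, °C at interfaces.
- Global-fit search bounds (defaults, overridable): L, D, E over wide log
  ranges (10⁻⁶–10⁸/10⁻⁹–10⁷/10⁻⁶–10⁹); ΔS° ∈ [0.05, 0.6]; ΔH°c ∈ [0, 20]
  kcal·mol⁻¹ and |ΔS°c| ≤ 0.06 kcal·mol⁻¹·K⁻¹ — the coupling energetics
  act on a perturbative scale well below the main sensor's.
- Fit determinism: a given seed is bit-reproducible; the local-descent
  candidate is seed-independent.
- Problem sizes: landscape grids of 15 × 12 (V × T) for fit comparisons,
  1000–1500 random draws for the enumeration property, 5-ms sampling for
  minute-scale regime simulations and 0.1-ms sampling for tail-kinetics
  fits — sizes at which every documented check runs in seconds to a few
  minutes on one core.

## Known limitations

- Absolute reproduction of the published landscapes is impossible: their
  L, D, E, ΔS°c values are unpublished, so all three regimes here are
  constraint-consistent refits, and the published fold changes between
  stages (72.5× E, 271.9× L, 32,733× D, …) are direction-checked only.
- The red pin set is infeasible at |z| = 0.74 (above); the ~8.5% worst-pin
  residual is a property of the pin set, not of the optimizer.
- Transient time courses of the regime-switch simulations are qualitative:
  no rate constants are published, so only equilibrium behavior is
  data-constrained.
- The eight-state scheme has no Ca²⁺ modulation and no more-than-8-state
  extensions; mutants enter only as alternative parameter sets.
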