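# Methods

## The model

The package implements a single-compartment Hodgkin–Huxley model of the
dorsal cochlear nucleus (DCN) fusiform neuron, the principal projection
neuron of that nucleus. Fusiform cells fall into two firing phenotypes —
*active* (regular spontaneous firing at rest) and *quiet* (silent) — set
by the density of an inwardly rectifying potassium conductance. The
model carries six conductances on a 20 × 20 μm cylinder (lateral area
π·d·L ≈ 1.257 × 10⁻⁵ cm², no end caps, the single-section convention of
compartmental simulators; specific capacitance 1 μF/cm²):

| current | density (mS/cm²) | reversal (mV) | role |
|---|---|---|---|
| I_Na (m³h) | 80 | +50 | spike upstroke |
| I_Kd (n⁴) | 20 | −81.5 | spike repolarization |
| I_NaP (p) | 0.1 | +50 | subthreshold depolarizing drive, activity threshold |
| I_Kir (w) | 0.5 active / 1.0 quiet | −81.5 | sets RMP, quiet/active switch |
| I_h (HCN) | 0.54 (0.5 in the RMP maps) | −43 | input-resistance control, sag |
| I_leak | 0.15 | −51.32 | Na⁺-permeable background depolarization |

Membrane current is positive outward; injected current positive
depolarizing. Each gate obeys dx/dt = (x∞(V) − x)/τ(V).

### HCN kinetics

I_h = g_h·(0.5·A_h1 + 0.5·A_h2)·(V − E_h), with two activation
variables sharing one steady state, A∞(V) = 1/(1 + exp((V + 87)/8.9)),
and distinct voltage-dependent time constants:

    τ_h1(V) = 100 + exp((V + 183.6)/30.48)                       [ms]
    τ_h2(V) = 700 + exp((V + 188.6)/11) / (1 + exp((V + 105)/5.5))

Around −110 mV these give ≈110 ms and ≈1.6 s, matching the fast and
slow activation components measured in fusiform neurons (fast ≈200–300
ms, slow ≈1.4–1.9 s). The algebraic form of the two τ expressions is
recorded as a parse identifier in the kinetics configuration so the
choice is explicit and swappable. Constraints any alternative must
satisfy: strictly positive on [−160, 0] mV (validated at construction),
τ_h2 > τ_h1 over [−120, −60] mV, and the magnitudes above.

### Na, Kd, NaP, Kir kinetics

These channels' detailed kinetics are not a contribution of this model
family (the fusiform literature defers them to earlier cochlear-nucleus
models), so they are configuration data (`ChannelKinetics`, YAML
round-trippable), with defaults built as follows:

- **Na**: Rothman–Manis-style cochlear-nucleus forms for the time
  constants; activation V½ = −36 mV (k = 7), inactivation V½ = −65 mV
  (k = 6).
- **Kd**: n⁴ with V½ = −28.20 mV, k = 12.98 mV; bell-shaped τ_n
  (0.5–3 ms).
- **NaP**: p with V½ = −42 mV, k = 3 mV, τ = 1 ms, no inactivation.
- **Kir**: w with V½ = −83.31 mV, k = 10.81 mV (activated by
  hyperpolarization), fixed τ = 0.5 ms.

The Kd and Kir steady-state placements were solved (four-parameter root
find on the steady-state current balance) so that the sodium-zeroed
model sits exactly on its four defining operating points: RMP −52.1 mV
(g_h = 0.5, g_Kir = 0) and −63.4 mV (g_Kir = 1), −58.5 mV (g_Kir = 0.5,
g_h = 0) and −55.6 mV (g_h = 1). The Na/NaP placements were chosen so
the quiet→active destabilization occurs when the sodium-zeroed resting
potential crosses ≈ −58 mV, inside the −59/−57 mV activity-threshold
window attributed to I_NaP in this cell type; with these defaults the
active preset fires at ~26 Hz and the quiet preset is silent. All four
placements are ordinary Boltzmann parameters in the configuration file;
swapping in a different companion parameterization changes nothing
structural.

## Integration

Exponential Euler for all seven gates *and* for V (conductance form
c_m dV/dt = −G_tot(V − V_inf)), fixed dt = 0.1 ms, initial potential
−65 mV with gates at steady state, and a 4 s settle before every
measurement window. Exponential Euler on V is exact for the passive RC
membrane and unconditionally stable through the spike's sodium
transient; a plain forward-Euler voltage update is unstable at this dt
during spikes (membrane time constant falls below dt), which is why the
voltage update is exponential rather than forward. Accuracy guards in
the test suite: passive-RC error < 0.1 mV against the closed form;
halving dt moves steady-state voltages by < 0.05 mV; the simulated
resting potential agrees with an independent bisection root of the
steady-state current balance to well under 0.5 mV across random
subthreshold parameter sets. Voltage clamp is ideal (zero series
resistance) and reports total ionic current, outward positive. A
blow-up detector aborts (with the step index) if V leaves [−200, +100]
mV; in batch scans, blown cells become NaN instead of aborting the
scan. The integrator core is vectorized over batches of cells, which is
what makes 2-D scans and population pipelines tractable at pure-Python
speed.

## Protocols and measurements

- **RMP**: both sodium conductances set to zero, no injected current,
  potential read at the end of a 1 s sweep after the settle.
- **Spontaneous activity**: full model, 1 s, no injected current; spike
  = upward crossing of −10 mV with 1 ms refractory (the threshold is
  far above all subthreshold dynamics, so its exact value is
  uncritical). *Active* iff rate > 0.5 Hz, strictly; 0.5 Hz exactly is
  quiet.
- **Input resistance**: current clamp, slope of the V–I line
  (−20 pA-style steps), or voltage clamp, 1/slope of the I–V line in
  [−80, −65] mV; for the model maps, R_in is the steady-state ΔV/ΔI for
  a single −20 pA step from rest on the sodium-zeroed model (step held
  3 s so the slow HCN gate settles).
- **Sag**: V_steady − V_peak during a hyperpolarizing step (−100 pA,
  3 s, sodium-zeroed); steady state = mean of the last 5% of the step.
- **Pharmacology emulation**: ZD7288 → g_h = 0; Ba²⁺ → g_Kir = 0;
  TTX → g_Na = g_NaP = 0; low-Na → E_leak shifted −16.5 mV (the
  measured −49.7 → −66.2 mV shift). Blocker-sensitive currents are
  isolated by pointwise subtraction of before/after traces on matching
  grids.
- **Tail activation curve**: long conditioning steps (≥ 5× the slowest
  HCN time constant over the step range; 8.5 s default), repolarization
  to −65 mV, tail amplitude = peak |I| within 50 ms after
  repolarization with two-sample smoothing, normalized to the maximum.
  Applied to the ZD-subtracted (pure I_h) traces the curve is
  proportional to A∞ of the step potential. For steps *above* the
  holding level the tail relaxes away from zero and the windowed peak
  slightly overestimates the small activation values; over the
  conventional −120…−65 mV range the curve matches A∞ to < 0.3%.
- **Fits**: Boltzmann a(V) = A/(1 + exp((V − V½)/k)) (optional offset),
  initialized at the half-maximum crossing, bounded; bi-exponential
  A_f·e^(−t/τf) + A_s·e^(−t/τs) + C with τf < τs enforced by ordering,
  log-linear tail initialization, and a degeneracy flag when
  τs/τf < 1.5. Non-convergence raises with diagnostics.
- **LJP**: true V = measured V − 10 mV (K-gluconate internal); a
  metadata flag prevents double correction.

### Conductance recovery

The experimental slope conductance of I_h between −100 and −75 mV is an
*effective* conductance: the slope of g_h·A∞(V)·(V − E_h) carries the
term g_h·A∞′(V)·(V − E_h) and runs 0.8–1.8× g_h across that window.
Known-truth recovery therefore uses chord estimates on the isolated
steady-state currents at −120/−110/−100 mV, dividing by the activation
curve and driving force (`ih_conductance_from_subtraction`), and the
same for the Ba-sensitive Kir current; the residual current's I–V slope
over [−80, −70] mV (where Kd is < 1% of the leak) gives g_leak and its
zero crossing E_leak. On a noise-free synthetic population this
pipeline recovers all three conductances within 0.2% and E_leak within
0.01 mV.

## Parameter-space scans

Two parameters at a time, each over [0, 2× baseline] unless an explicit
axis is given (reversal potentials may be axes too, bounded to
[−90, −30] mV for E_leak). Metrics: RMP (sodium-zeroed), firing rate
(full model), R_in, sag. Every grid cell is evaluated by the same
batched code path as a single run and is bit-identical to it (tested).
Firing labels are computed for every grid so the quiet/active boundary
can be extracted: adjacent cells with differing labels contribute the
midpoint between their centers; checkerboard-like grids are flagged as
multivalued, single-class grids return an empty boundary with a
warning. Analysis drivers use 15–21 points per axis — the maps are
smooth and this resolves them fully while keeping each scan around a
minute; the resolution is configurable.

## Synthetic population

The generator emulates the two experimental cohorts at the level of
per-class conductance statistics, not raw traces:

- g_h ~ Normal, mean 5.0 nS (quiet) / 6.9 nS (active), SD = the printed
  cohort SEM × √n (≈2.1 nS) — the cohort spread, not the SEM itself;
- g_Kir ~ lognormal around the class preset density converted to nS
  (12.6 quiet / 6.3 active at the model area), 20% CV — the per-neuron
  Kir spread is not experimentally constrained and is a declared
  assumption;
- g_leak ~ lognormal around the model's baseline leak (1.9 nS), 20% CV.
  The experimental cohort leak values (8.0/7.1 nS) are inconsistent
  with the model's own leak density: at the model's area they
  depolarize every cell into firing and no quiet phenotype exists, so
  they are not the default (they remain reachable through the config).

Draws are truncated at zero by resampling (no point mass at 0). Every
neuron is simulated (1 s spontaneous activity) and labeled by the
strict 0.5 Hz rule; recordings get additive white Gaussian noise on the
recorded channel only, seeded and reproducible.

What the generator does *not* emulate: correlated co-regulation of
conductances within a neuron (draws are independent given the class),
series-resistance and seal artifacts, inter-animal structure, and
cell-size variability. Consequently, passing recovery tests show the
*pipeline* is correct on model-generated data, not that the model
captures every property of slice recordings.

### The 50% g_Kir-share rule

Classifying neurons as quiet when g_Kir ≥ 50% of the subthreshold total
(g_Kir + g_h + g_leak) reproduces the experimental finding at the class
presets and for most draws, but in the model it is an approximation:
near rest the leak is roughly an order of magnitude more depolarizing
per nS than the (mostly deactivated) HCN conductance, so the model's
true quiet/active boundary in composition space sits at a g_Kir share
of ~43–51% depending on the g_h:g_leak mix. Neurons drawn close to the
boundary — e.g. with an unusually small g_h, which shrinks the total
without moving the resting potential much — can fall on opposite sides
of the rule and the simulation (11/12 agree in the default seeded
population). The strict rule/label equivalence is therefore asserted on
the dispersion-free population, and the compositional signature (g_h%
falling as g_Kir% rises, absolute values uncorrelated) on the
dispersed one.

## Numerical and design choices

- Gates are initialized at their steady state for V₀ = −65 mV (the
  initial potential is given by convention; the gate initialization is
  the natural completion).
- Degenerate inputs: all-zero conductances are legal (pure capacitor,
  forward-Euler voltage update in that limit).
- Dynamic clamp is emulated exactly: an artificial conductance g_art
  (nS) with native HCN kinetics and reversal equals a density increase
  of g_art/area, so titration series run as batches; `run_dynamic_clamp`
  with g_art = 0 is bit-compatible with a plain run.
- The alternative I_h magnitude estimator (steady-state minus onset
  current) is provided (`ih_from_onset_difference`); it and the
  subtraction estimator agree on isolated currents by construction.
- Problem sizes in the shipped drivers (grids of 15–21 per axis, 8.5 s
  conditioning steps, 12-neuron populations) were chosen as the
  smallest that leave the measured quantities visibly converged
  (dt-halving and hold-doubling move results by far less than the
  tolerances asserted in the tests); all are arguments, not constants.

## Known limitations

- Single compartment; no morphology, temperature scaling, stochastic
  gating, or calcium dynamics.
- The spiking-current parameterization is calibrated, not measured: the
  four subthreshold operating points and the activity-threshold window
  pin it, but spike shape and the exact firing rate of the active
  preset (~26 Hz here) are not fitted quantities.
- The model's composition-space firing boundary only approximates the
  empirical 50% g_Kir-share rule (see above).
- Voltage clamp is ideal; access-resistance artifacts of real
  recordings are intentionally out of scope.
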