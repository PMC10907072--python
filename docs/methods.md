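# Methods

## Model structure

The circulation is a single ring of six volume compartments — LV, AO, VC,
RV, PA, PU — connected by six resistive segments (aortic valve, systemic
resistance, tricuspid valve, pulmonary valve, pulmonary resistance, mitral
valve).  The four valve segments are ideal diodes with zero forward
pressure loss: flow is clamped to zero whenever downstream pressure exceeds
upstream pressure.  Septal interaction, arterial inertia and the atria are
deliberately absent; their omission keeps the right-hand side cheap enough
for the 20 kHz real-time tick the model emulates.

Passive compartments obey a linear pressure-volume relation above their
unstressed volume and are clamped to zero pressure below it.  The total
volume (24 mL) splits into 3 mL stressed and 21 mL unstressed; the
unstressed volume is distributed over the four passive compartments in
proportion to compliance, and the ventricles carry none (their
zero-pressure volume is taken as zero, consistent with the elastance
ventricle's V₀ = 0).  The default initial state puts 0.23 mL in each
ventricle and spreads the remaining stressed volume over the passive
compartments proportional to compliance, so all passive compartments start
at a common pressure.  Both splits are configurable.

All internal quantities are SI (Pa, m³, s).  The configuration loader
accepts prefixed unit strings (`"175 GPa·s/m^3"`, `"24 mL"`, `"50 us"`)
and normalizes on load.  The end-systolic elastances are stored as
E_ES,LV = 170 GPa·m⁻³ and E_ES,RV = 40 GPa·m⁻³ — the reading that yields
physiological ventricular pressures at the stated initial LV volume; only
their ratio (40/170) enters the hybrid mode, where RV pressure is LV
pressure scaled by it.  The printed compliance unit is read as m³·Pa⁻¹.
Both readings are logged at configuration time and overridable.

## Integration

The production integrator is explicit Euler at dt = 50 µs (20 kHz),
matching a real-time control loop: the diode clamp is re-evaluated every
tick and no event detection is attempted.  A donor clamp limits each
segment's flow to the volume its donor compartment can supply in one step,
which enforces non-negative volumes under the fixed step.  Total volume is
conserved to machine precision by construction (each flow enters the
bookkeeping once with each sign); over 50 paced cycles the measured drift
is ~3×10⁻¹⁴ relative.

`reference_solution` integrates the identical right-hand side with an
adaptive embedded Runge-Kutta method at rtol 10⁻⁹.  It exists purely as a
verification oracle: the fixed-step trajectory converges to it with
observed order 1 (error ratio ≈ 2.0 under dt halving), and on a
two-compartment RC reduction both match the closed-form exponential
relaxation (time constant R·C₁C₂/(C₁+C₂)) to better than 10⁻⁶ relative.

Periodic steady state is declared when the largest cycle-to-cycle volume
change over all compartments and all samples within a period falls below
0.1 µL.  From the default initial partition with the elastance ventricle
this takes 62 cycles at the 20 kHz tick; sweeps warm-start each afterload
point from the previous point's final state (as on the bench, where loads
are applied in descending order), which cuts this to a few tens of cycles.
Non-convergence is flagged on the record, never raised.

## The virtual trabecula

The muscle emulator produces total stress
σ(L, t) = e(t)·σ_active(L) + σ_passive(L):

- **Activation** e(t) = (1 − exp(−t/τ_r))·exp(−t/τ_d), normalized to unit
  peak, with τ_r = 30 ms and τ_d = 110 ms at 2 Hz — a rat-trabecula-like
  twitch time course at 32 °C.  A sampled waveform (CSV of one period) may
  be substituted.
- **Active stress-length**: linear from zero at the slack length
  (0.8 L₀) to σ_max = 50 kPa at L₀.
- **Passive stress-length (EDSLR)**:
  σ_p = a·(exp(b·(L/L₀ − 0.8)) − 1) with defaults a = 3 Pa, b = 30,
  i.e. ≈1.2 kPa at L₀ and falling steeply below it.

The EDSLR steepness (b = 30 rather than a shallower curve of the same
anchor) is a deliberate calibration.  The emergent end-diastolic length of
the closed loop sits where the pulmonary venous pressure balances the
muscle's passive Laplace pressure, and its *stability* depends on the
passive slope beating the destabilizing feedback loop
(stress → RV drive → venous return → EDL → stress).  A compliant-but-steep
EDSLR places the operating point at 0.95–1.0 L₀ across the healthy
afterload range — engaging the L₀ cap at the highest loads, which is why
the cap exists — and makes it an attractor.  With a shallow passive curve
the muscle has no stable operating point near L₀ and slides to its slack
length at every load.

Geometry: the muscle's cross-section is the ellipse of its two measured
diameters (defaults 392 × 376 µm → 0.1158 mm²; with L₀ = 3.56 mm the
muscle volume is 0.412 mm³).  The assumed ventricular wall thickness is
h = 1.1 mm and the reference radius r₀ derives from the initial LV volume
through the sphere relation (0.23 mL → 3.80 mm), so the commanded length
is exactly L₀ at the initial volume.  Only h/r enters the pressure map.

## Protocols

**Closed loop** (hybrid mode): each tick maps LV volume → radius →
commanded length (capped at L₀) → muscle stress at the current twitch
phase → LV pressure by Laplace; the circulation then advances one Euler
step.  The map is memoryless, so length and stress traces are
reconstructed from the recorded volumes after the run.  End-diastolic
length is an output; the model starts restretching while active stress is
still decaying (at ≈5 % of the twitch peak at high loads), i.e. before
full relaxation — the behavioral signature that distinguishes it from the
comparator.

**Three-element Windkessel comparator**: characteristic resistance,
compliance and peripheral resistance correspond to R_AV, C_AO, R_SYS.
Each cycle runs isometric rise at the experimenter-set EDL → ejection
against the Windkessel (C·dP_AO/dt = Q − P_AO/R_p, venous pressure zero) →
isometric relaxation at end-systolic length → linear restretch to EDL over
150 ms, triggered when active stress falls below 10 % of the cycle's
active peak (the trigger is set so the ramp completes before the next
stimulus at 2 Hz; a 5 % trigger would spill past the cycle boundary).
After restretch the length is held at EDL until the next stimulus — the
conventional method models only the shortening phase, so a passive LV
pressure exceeding a low arterial pressure during the hold must not
shorten the muscle.

With the closed-loop model's venous and pulmonary compartments clamped and
the mitral path disabled, a single twitch reproduces the comparator's
ejection trajectory to machine precision (same tick, same discretization) —
the two implementations are the same model on the overlapping circuit.

**Sweeps** apply a descending afterload grid
{800, 500, 300, 175, 115, 50, 30} GPa·s·m⁻³ (covering both reported
ranges, including the 175/115 validation values), warm-starting each point.
Interleaved isometric contractions (an experimental drift control) are
supported in principle but off by default; in simulation there is no
instrument drift and they do not alter the attractors.

**In silico mode** replaces both ventricles with time-varying elastance
sources P = e(t)·E_ES·V.  Its end-systolic points lie on the line through
the origin with slope E_ES, and raising R_SYS from 50 to 500 GPa·s·m⁻³
raises end-diastolic volume and peak LV pressure together — the
closed-loop coupling signature used for parameter validation.

## Energetics

Work per twitch is the shoelace area of the closed (σ, L) polygon
(counterclockwise = shortening under high stress = positive), in joules
after multiplying by cross-sectional area; the loop width over L₀ is the
shortening extent.  Thermopile voltage converts to heat per twitch by
dividing by sensitivity (4000 V/W) × stimulus frequency (2 Hz).  Active
heat is total minus basal minus stimulus artifact, floored at zero with a
warning (a negative value indicates inconsistent measurements).  Enthalpy
is work + active heat, exactly; efficiency is work/enthalpy, in [0, 1).
Presentation fits are ordinary least squares polynomials (order 2 or 3) on
the predictor or its logarithm.

Because no calorimeter exists in simulation, the virtual muscle carries a
heat surrogate: active heat per twitch = c_h·A·L₀·⟨σ_active⟩ with the
cycle-averaged active stress (i.e. proportional to the tension-time
integral) and c_h = 0.25, chosen to give peak mechanical efficiencies in
the 0.2–0.4 band typical of rat trabecula work-loops.  The synthetic
calorimeter fixtures additionally model basal heat as
b₀ + b₁·(shortening) + b₂·⟨|dL/dt|⟩ — a linear stand-in for the measured
dependence of quiescent-muscle heat on the rate and extent of length
change — plus a constant stimulus artifact; the exact experimental
correction lives in instrument-specific calibrations and is not
reproduced.

The fixture generator is the package's data emulator: it runs the virtual
muscle, converts the known per-twitch heat schedule to a thermopile
voltage staircase via the inverse of the heat conversion, adds seeded
Gaussian noise and linear drift, and writes the ground truth alongside.
At zero noise the analysis pipeline recovers the schedule exactly; with
noise it recovers it within the per-twitch averaging bound.  What passing
these tests shows is that the *pipeline* is self-consistent — not that the
heat surrogate reproduces any particular muscle's calorimetry.

## Known limitations

- **No force-velocity (Hill) dependence** — out of scope by design.  This
  has a real consequence: a velocity-independent muscle cannot shed stress
  during rapid ejection, so the destabilizing afterload-preload feedback
  wins below R_SYS ≈ 200 GPa·s·m⁻³ and the closed loop slides to a
  near-slack, near-zero-work state (monotonically, so the EDL-vs-load
  ordering survives).  Physical muscles, which do shed stress with
  velocity, sustain stable loops down to 30 GPa·s·m⁻³.  The degenerate
  points are flagged non-converged in sweeps.
- The pressure-slaved RV has no volume feedback; its volume is a neutral
  direction regulated only indirectly (and it is the vehicle of the
  collapse above).
- Spherical thin-wall geometry, no septal interaction, no inertance, no
  atria; valve chatter is possible at the tick scale and is left to the
  diode clamp.
- The 2 Hz / 32 °C operating point is assumed throughout the defaults;
  other pacing rates require re-checking that relaxation and restretch fit
  inside one period.

## Problem sizes

Tests run protocol physics at a 5 kHz tick with reduced grids; the
acceptance suite and `scripts/acceptance.py` run the production 20 kHz
tick, full seven-point sweeps with up to 300 cycles per point, 50-cycle
conservation runs, and five-point in silico validation (about one minute
end to end).
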