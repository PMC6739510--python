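# Methods

## Model

`wkloop` simulates a muscle-loading rig in which a one-dimensional cardiac
muscle contracts against the input impedance of a lumped arterial model.
The coupling chain, evaluated every time step, is

1. muscle force `F(t)` → wall stress `σ = F/(πd²/4)`;
2. stress → ventricular pressure by the thin-walled-sphere (Laplace)
   relation `P = 2σh/r`, with chamber radius linear in muscle length,
   `r = r_ref·L/L_ref`, hence the cubic volume law `V(L) ∝ L³`;
3. an ideal aortic valve: closed while `P ≤ Pa` (`Q = 0`, `Pa = Pp`),
   open while the algebraic flow `Q = (P − Pp)/Zc` is positive
   (`Pa = Pp + Q·Zc`);
4. the three-element Windkessel: compliance state
   `C·dPp/dt = Q − Pp/Rp`;
5. ejected volume and prescribed diastolic refill inflow update the chamber
   volume, which maps back to a muscle length command.

Assumptions inherited from the sphere mapping: constant wall thickness
(no wall thinning during ejection), spatially uniform load, no inertance
(3-element, not 4-element, arterial model), an ideal valve with zero
forward drop and zero leak, and a purely kinematic refill (no atrium or
mitral valve).

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| `Rp` | peripheral resistance | preset (14.5 normotensive) | GPa·s·m⁻³ |
| `C` | arterial compliance | preset (32) | pm³·Pa⁻¹ |
| `Zc` | characteristic aortic impedance | preset (0.5) | GPa·s·m⁻³ |
| `L0`, `diameter` | muscle optimal length, diameter | per preparation | mm |
| `r_ref` | chamber radius at `L_ref` | 5.0 | mm |
| `h` | wall thickness | 0.15 | mm |
| `stim_hz` | stimulus rate | 1 or 5 | Hz |
| `refill_rate` | diastolic inflow | 0.4·V_ED·f/0.3 | µL/s |
| `refill_trigger_fraction` | relaxation level that enables refill | 0.05 | – |
| `dt` | engine step | 50 | µs |

Compliance is interpreted as m³·Pa⁻¹ (the literature sometimes prints a
stray s⁻¹); with the normotensive values this gives a diastolic decay
constant `Rp·C = 0.464 s`, in the physiological 0.3–0.5 s range.

**Ventricle sizing.** The mapped ventricle must be large enough that
ejection self-limits: stopping flow requires charging the arterial
compliance from diastolic to near-peak ventricular pressure, which costs
roughly `C·ΔP` of volume. With rat-scale compliance (32 pm³·Pa⁻¹) and a
chamber smaller than ~0.3 mL, that charge exceeds the chamber volume and a
prescribed-force (replay) beat empties the ventricle completely — the
simulation has no steady loop. The defaults `r_ref = 5.0 mm`
(V_ref ≈ 0.52 mL) and `h = 0.15 mm` were chosen so that peak ventricular
pressure (~4.5 kPa for a 66 kPa twitch) sits inside the self-limiting
regime across the studied afterload range (`Rp` from 5 GPa·s·m⁻³ up),
yielding bounded four-phase loops with 4–14% shortening. Larger `h`
(higher pressures) is usable at high `Rp` but collapses the chamber at low
`Rp`; both values are configuration-exposed.

## Numerical scheme

The engine is a deterministic fixed-step loop (default 20 kHz) mirroring a
real-time implementation: the causal order force → pressure → valve → flow
→ length is evaluated once per step, with no hidden randomness, so
identical configurations give bit-identical output.

* **Closed valve:** `Pp` decays by the exact exponential
  `exp(−dt/(Rp·C))` (machine-precision accurate; the trapezoidal variant
  exists for cross-checks).
* **Open valve:** `Pp` advances by the A-stable trapezoidal (implicit
  midpoint) rule with the driving pressure taken as the average of the
  force source at the step's endpoints; the volume update uses the
  trapezoid of the start- and end-of-step flows. This keeps the per-step
  error second order where the dynamics are smooth.
* **Transfer-function path:** the input admittance
  `Y(s) = (1 + sRpC)/((Rp+Zc) + sRpCZc)` is also provided as a bilinear
  (Tustin) discrete filter; Tustin matches the DC gain exactly, its pole
  is stable for every valid parameter set, and it agrees with the
  state-space stepping to within 0.1% on smooth pressure traces (the two
  are the same trapezoidal rule in different coordinates).
* **Hill-muscle ejection is solved implicitly.** During ejection the
  shortening velocity, force–velocity factor, ventricular pressure and
  flow form an algebraic loop whose gain at 50 µs is far above unity;
  updating velocity with a one-step lag (the naive causal choice) makes
  the valve chatter with period two. On the Hill hyperbola the loop
  reduces to a quadratic in the normalised velocity with a unique
  non-negative root, which the engine solves in closed form each step
  (plus one Heun re-solve at the predicted end state). Replay mode has no
  force–velocity feedback and keeps the plain explicit path.
* **Refill** runs at the configured rate, tapers to zero over 5 ms as the
  chamber approaches end-diastolic volume (a step change in commanded
  velocity is unrealisable by a physical motor and would spoil step-size
  convergence at the completion instant), and snaps shut once the deficit
  is below 10⁻⁷ of the end-diastolic volume so the refill phase
  terminates cleanly. End-diastolic length is restored to well within
  10⁻⁶·L0 before the next stimulus.
* **Valve tie-break:** at `P = Pa` exactly the valve stays closed (strict
  inequality), avoiding zero-gradient chattering.
* **Parameter interventions** default to taking effect in the first
  diastole at or after their scheduled time (matching how a rig operator
  changes a dial between beats); immediate application is available.
* **Degenerate inputs:** non-positive lengths, volumes or NaNs abort with
  a diagnostic naming the offending update and simulation time; an
  undersized chamber (see sizing above) is the canonical way to trigger
  this.

Halving `dt` changes every logged state by well under 0.05% in all three
loading modes; one replay beat agrees with an independent adaptive
event-detecting integration (`scipy.integrate.solve_ivp`, Radau,
rtol 10⁻¹⁰) to better than 0.1% in `Pp`, `Q` and `L`; and the per-beat
energy audit `∮P·Q dt = ΔE_C + ∮Q²Zc dt + ∮Pp²/Rp dt` closes to ~0.01%.

## Force sources

**Replay** feeds back a prescribed twitch, invariant with shortening. The
synthetic twitch is a double exponential
`a(e^{−t/τ_fall} − e^{−t/τ_rise})` scaled to a stated peak (default
3.5 mN, τ_rise 40 ms, τ_fall 120 ms at 1 Hz), consistent with recorded
isometric twitches of rat trabeculae; arbitrary two-column (time, force)
text traces can be loaded instead.

**Hill surrogate** supplies load-dependent force for closed-loop studies:
total stress = activation(t) · σ_max · fl(L) · fv(v) + passive(L), with a
parabolic force–length factor (half-width 0.35·L0), the Hill hyperbola
(`a/F0 = 0.25`) for shortening, a linear ramp to a 1.1 cap for
lengthening, an exponential passive term (slack at 0.85·L0), and a
double-exponential activation waveform normalised to peak 1. σ_max
defaults to 66 kPa so the isometric twitch of the reference muscle
(0.26 mm diameter) peaks near 3.5 mN. Two kinetic presets are provided:
`body_temperature` (rise 12 ms, fall 30 ms, v_max 5 L0/s; suits 5 Hz
pacing) and `room_temperature` (rise 60 ms, fall 180 ms, v_max 1.5 L0/s;
suits 1 Hz). The model is deliberately memoryless — it has no calcium
handling, restitution or length-dependent activation — so multi-beat
transients reflect only the arterial-state dynamics, not intrinsic muscle
memory; observed adaptation to a resistance step is correspondingly
faster-settling than in living preparations.

**Isotonic controller** reproduces the flat-topped protocol: isometric
rise until the afterload is reached; shortening with the force–velocity
relation inverted in closed form so force stays on the afterload
(deviation well under 0.5%); isometric relaxation once no non-negative
velocity sustains the load; constant-velocity re-lengthening (over 15% of
the period) after relaxation. Afterloads above the peak isometric force
leave the beat isometric and set a flag rather than failing.

## What the simulations do and do not show

The replay and Hill sources are synthetic stand-ins for a living
trabecula. Passing tests demonstrate that the *loading system* behaves
correctly — circuit limits, energy conservation, hybrid-phase logic,
monotone loop narrowing with peripheral resistance, compliance
insensitivity at long `Rp·C`, disease-preset orderings, unimodal
work–afterload relations — under force inputs with realistic amplitude and
kinetics. They do not validate any biophysics of cardiac muscle itself:
real preparations add restitution, length-dependent activation, and
beat-to-beat variability that the surrogates lack.

## Design choices

* The statement "aortic and peripheral pressure are equal in diastole"
  plus the series-resistor circuit fixes the Windkessel equations; the
  discrete path uses Tustin (A-stable, exact DC gain) and the state-space
  path exact/trapezoidal updates. Either could serve as the engine; the
  state-space path is the default because the valve logic is explicit
  there.
* End-systole is defined as the valve-closure instant (the unambiguous
  choice in simulation); for isotonic beats, as the end of shortening.
* Work is reported both as `|∮F dL|` (J) and as the stress–length area
  (Pa·m) to serve both unit conventions in use.
* The refill trigger ("diastole has begun") is active stress falling below
  5% of the previous beat's peak, evaluated on the isometric (v = 0)
  envelope so that lengthening transients cannot re-arm it.
* Sweeps run each value to periodic steady state (beat-to-beat change of
  peak stress and shortening below 0.5%, 40-beat cap) and carry the
  circuit state between values, like an experimenter turning one dial on a
  continuously beating preparation.

## Problem sizes

Default runs used throughout tests and the acceptance script: 12 s of
1 Hz replay loading (240 000 steps) for steady-state metrics; 6-point
resistance sweeps to steady state; a 20 s Hill run for the
resistance-step transient; 1 s runs per disease preset at 5 Hz. All are
exact reproductions of the respective protocols at full 20 kHz resolution.

## Known limitations

* Thin-wall, constant-thickness sphere; no thick-wall or finite-element
  ventricle, no sarcomere heterogeneity.
* Three-element Windkessel only; no inertance, no wave propagation.
* No preload (Frank–Starling) protocols, atrial kick or valve
  regurgitation.
* The Hill surrogate's parameters are generic rat-like values, not fits
  to any particular preparation.
* At extremely low peripheral resistance combined with high compliance the
  chamber can empty faster than any refill policy restores it; the engine
  reports this as a diagnostic abort rather than guessing.
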