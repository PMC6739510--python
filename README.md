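# wkloop

Virtual work-loop experiments on isolated cardiac muscle, loaded in real
time by a three-element Windkessel model of the arterial circulation.

## The problem

Isolated cardiac trabeculae — thin strands of ventricular muscle — are the
workhorse preparation of cardiac mechanics, but they are traditionally
loaded with *time-invariant* afterloads: either isometric contractions or
"flat-topped" work-loops in which the muscle shortens against a constant
force. Neither resembles the load a ventricle actually works against,
which is the dynamic input impedance of the arterial tree. `wkloop`
simulates a loading rig that closes that gap: at every 50 µs step the
muscle's force is converted to an equivalent ventricular pressure, fed to a
lumped arterial model, and the resulting ejection flow is converted back to
a muscle shortening command. The muscle then traverses realistic
stress–length loops, adapts over beats to abrupt changes in the arterial
parameters, and can be confronted with "diseased" (hypertensive,
hypotensive) arterial loads.

## The model

* **Muscle → ventricle (Laplace mapping).** Muscle force `F` at length `L`
  maps to wall stress `σ = F/(πd²/4)` and to the pressure of a thin-walled
  elastic sphere, `P = 2σh/r`, with radius proportional to muscle length
  (`r = r_ref·L/L_ref`), so chamber volume obeys the cubic law
  `V(L) ∝ L³`.
* **Arterial load (3-element Windkessel).** Characteristic aortic
  impedance `Zc` in series with peripheral resistance `Rp` parallel to
  arterial compliance `C`; input impedance `Z(s) = Zc + Rp/(1 + s·Rp·C)`.
  The aortic valve is an ideal diode: closed while `P < Pa`, during which
  `Pa = Pp` decays exponentially with time constant `Rp·C`; open while
  ejection flow `Q = (P − Pp)/Zc > 0`.
* **Cycle.** Beats are triggered at a fixed stimulus rate; once the muscle
  relaxes below a trigger fraction of its previous peak stress, a
  prescribed diastolic volume inflow restores the end-diastolic length.
* **Force sources.** A prescribed twitch trace (replay mode, the classic
  "dry run" validation), a Hill-type active-muscle surrogate
  (activation × force–length × force–velocity + passive stress) for
  closed-loop adaptation studies, and an isotonic controller that produces
  the classical flat-topped loops for comparison.

Parameters follow the cardiac literature's units at the configuration
boundary (GPa·s·m⁻³, pm³·Pa⁻¹, mN, mm, kPa) and strict SI internally.
Presets ship for normotensive (`Rp = 14.5 GPa·s·m⁻³`, `C = 32 pm³·Pa⁻¹`,
`Zc = 0.5 GPa·s·m⁻³`), hypertensive, hypotensive and a slow-twitch
room-temperature base load.

## Worked example

```python
import wkloop as wk

trab = wk.TrabeculaGeometry(L0=1.8e-3, diameter=0.26e-3)
vg = wk.default_ventricle(trab)
cfg = wk.SimConfig(
    geometry=trab, ventricle=vg,
    windkessel=wk.get_preset("normotensive"),
    cycle=wk.CyclePolicy(1.0, wk.default_refill_rate(vg, 1.0, trab.L0),
                         trab.L0),
    twitch=wk.synthesize_twitch(3.5e-3, 0.04, 0.12, 1.0),
    duration=12.0,
)
rec = wk.run(cfg)
m = wk.beat_metrics(rec, rec.n_beats - 1)
print(f"peak stress      {m.peak_stress/1e3:.1f} kPa")
print(f"shortening       {m.shortening_extent*100:.1f} % of L0")
print(f"stroke volume    {m.stroke_volume*1e9:.0f} uL")
print(f"work per beat    {m.work*1e6:.2f} uJ")
print(f"diastolic tau    {m.fitted_tau:.3f} s")
```

prints

```
peak stress      65.9 kPa
shortening       8.9 % of L0
stroke volume    128 uL
work per beat    0.44 uJ
diastolic tau    0.464 s
```

A 3.5 mN twitch over a 0.26 mm-diameter muscle is 65.9 kPa of wall stress;
against the normotensive impedance the muscle shortens 8.9% of its optimal
length per beat, ejecting 128 µL from the mapped ventricle and performing
0.44 µJ of mechanical work; the fitted diastolic decay constant recovers
`Rp·C = 14.5 GPa·s·m⁻³ × 32 pm³·Pa⁻¹ = 0.464 s` exactly.

The same experiment from the shell:

```sh
wkloop simulate examples/normotensive_replay.yaml --out run.csv --metrics m.json
wkloop sweep examples/normotensive_replay.yaml --param windkessel.Rp \
    --values 5,10,20,30,40,50 --out sweep.csv
wkloop presets
```

Other CLI commands: `step-experiment` (abrupt mid-run parameter change and
the resulting beat-by-beat adaptation), `compare-modes` (work–afterload
table for Windkessel-loaded vs flat-topped loops), `make-twitch`
(synthetic twitch trace files).

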