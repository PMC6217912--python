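# cathfidelity

Desk-scale toolkit for quantifying the measurement bias that a fluid-filled
catheter introduces into intravascular pressure recordings, relative to an
ideal tip-mounted ("wire") transducer.

Clinicians routinely measure blood pressure with fluid-filled catheters even
though two well-known artifact classes corrupt the recording:

1. **Obstruction.** The catheter body partially blocks the vessel and every
   narrower duct downstream of its tip, so the same flow must pass through an
   annulus of higher hydraulic resistance — pressure upstream (where the tip
   measures) is overestimated.
2. **Dynamic response.** The fluid column coupling the tip to the external
   transducer behaves as a second-order mass-spring-damper with natural
   frequency `f_n` and damping `ζ`: frequencies near `f_n` resonate, higher
   frequencies are low-passed. This suppresses the dicrotic notch, delays the
   apparent foot of the systolic upstroke, and inflates foot-to-foot pulse
   wave velocity (PWV) estimates.

The package reproduces both mechanisms on a reduced-order model of a
pulsatile flow phantom (a compliant 8 mm silicone tube driven at 60 beats/min
with a Windkessel afterload) and provides the analysis stack used to quantify
them.

## Components

| module | contents |
|---|---|
| `cathfidelity.waveforms` | synthetic pressure/flow generators (systolic upstroke, exponential diastole, damped 5.4 Hz dicrotic ring; seeded noise; bubble-type degradation) |
| `cathfidelity.vessel` | 1-D pulse-wave solver (mass/momentum + linear tube law, MacCormack scheme), Windkessel afterload, coaxial-catheter obstruction, `Re`/Womersley/Moens–Korteweg/annular-resistance closed forms |
| `cathfidelity.transducer` | catheter-manometer dynamics: `f_n = (1/2π)·√(πR²(dP/dV)/(ρl))`, `ζ = (4μl/R³)/√(ρlπ(dP/dV))`, time-domain RK4 distortion, analytic `|H(f)|` |
| `cathfidelity.analysis` | cycle features (P_s, P_d, pulse pressure, notch), intersecting-tangents foot and foot-to-foot PWV, zero-padded single-sided spectra, curvature-sum air-bubble QC (threshold 3.85) |
| `cathfidelity.pipeline` | end-to-end wire-vs-catheter comparison experiment, config (YAML/JSON), fixtures, JSON report |
| `cathfidelity.cli` | `cathfidelity synth\|simulate\|measure\|analyze\|compare\|fixtures` |

## Worked example

```python
from cathfidelity.pipeline import default_config, run_comparison

report = run_comparison(default_config())
d = report.data
print(f"peak overestimation (model):    {d['peak_overestimation_pct']:.1f} %")
print(f"peak overestimation (measured): {d['measured_peak_overestimation_pct']:.1f} %")
print(f"pulse-pressure ratio:           {d['pulse_pressure_ratio_pct']:.1f} %")
print(f"PWV wire / catheter @ 120 mm:   {d['pwv_wire']['0.12']:.2f} / "
      f"{d['pwv_catheter']['0.12']:.2f} m/s")
```

prints (default configuration, ~8 s on one CPU):

```
peak overestimation (model):    6.6 %
peak overestimation (measured): 31.7 %
pulse-pressure ratio:           73.9 %
PWV wire / catheter @ 120 mm:   6.02 / 6.87 m/s
```

Reading: the catheterized simulation overestimates the tip peak pressure by
6.6 % through the obstruction mechanism alone; passing that signal through
the underdamped nominal transducer (`f_n` = 40 Hz, `ζ` = 0.15) adds resonance
overshoot on the steep phantom upstroke, bringing the measured overestimation
to 31.7 %. The wire pulse pressure is 74 % of the catheter-measured one. The
wire-signal foot-to-foot PWV (6.02 m/s) sits on the Moens–Korteweg speed of
the tube (6.01 m/s), while heavily damped catheter-like signals inflate it.

Generate and inspect a synthetic waveform from the shell:

```sh
cathfidelity synth --out wave.csv
cathfidelity analyze --in wave.csv --report wave.json
```

`wave.json` reports P_s = 106.4 mmHg, pulse pressure 100.86 mmHg, a dicrotic
ring at 5.41 Hz, and a curvature sum of 7.33 (above the 3.85 QC threshold,
i.e. bubble-free).

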