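# Methods

This note documents the models behind `cathfidelity`, the defaults they
ship with, and the reasoning behind the design choices that were genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The system being emulated

The reference system is a pulsatile flow phantom: a piston pump drives water
(μ = 1.002 mPa·s, ρ = 998 kg/m³) at 1 Hz through a compliant silicone tube
(inner radius R_i = 8 mm, outer radius R_o = 9.5 mm, wall modulus
E_s = 384 kPa, wall density 1250 kg/m³) terminated by an adjustable
resistance and a compliance chamber. The working point is characterized by a
mean-velocity Reynolds number of 1308 (which pins the cycle-mean velocity at
U = Re·μ/(2R_i·ρ) = 0.0821 m/s) and a Womersley number of 20. Pressure is
sampled at 10 axial stations 20 mm apart near the distal end, with either a
tip-mounted pressure wire (radius 0.18 mm — treated as non-perturbing) or a
6F fluid-filled catheter (external radius R_c = 1 mm, lumen radius
R = 0.32 mm, length 800 mm, measured natural frequency 40 Hz and damping
coefficient 0.15) whose tip sits at z = 140 mm.

Two distinctive features of this rig matter for modelling: the systolic peak
is high (~106 mmHg) while the diastolic pressure is far below the
physiological range (~5 mmHg), so the pulse pressure (~101 mmHg) is nearly
the whole signal. That combination implies a fast, wave-dominated ejection
into a low-impedance runoff — not the compliance-buffered waveform of a real
arterial tree — and the package's defaults are chosen to live in that
regime.

## Synthetic pressure waveform

One cycle of period T is piecewise analytic, so each clinically meaningful
feature maps to exactly one parameter:

- systolic upstroke, `sin²` ramp from `p_dia` to `p_sys` over 0.25 T;
- systolic downstroke, `cos²` fall to an end-systolic shoulder at
  `p_dia + 0.35·PP` by 0.42 T;
- diastole, an exponential run-off (time constant 0.35 T) pinned to reach
  `p_dia` exactly at the cycle end, so min = `p_dia` and max = `p_sys` hold
  by construction;
- dicrotic ring, a damped sinusoid `−A·e^(−λt′)·cos²(πt′/2T_d)·sin(2πf_r t′)`
  starting at end-systole (t′ = 0). The leading minus makes the oscillation
  dip first (the notch) and rebound; the `cos²` taper takes it smoothly to
  zero at the cycle end so the tiled record is continuous.

Defaults: 60 beats/min, `p_sys` = 106.4 mmHg, `p_dia` = 5.54 mmHg (so the
pulse pressure is 100.86 mmHg), `f_r` = 5.4 Hz, decay λ = 3 s⁻¹, amplitude
A = 6 mmHg, 10 cycles at 100 Hz. The ring amplitude and decay are the one
place the operating point does not dictate a value; 6 mmHg (≈ 6 % of pulse
pressure) with λ = 3 s⁻¹ (2–3 visible oscillations) is a typical dicrotic
signature at this pulse pressure and leaves the amplitude contract intact.
Gaussian measurement noise is available but off by default; all stochastic
paths take an explicit seed.

The inlet flow is an asymmetric ejection pulse (`sin²` rise, `cos²` fall,
zero diastolic flow) whose height is scaled so the discrete cycle-mean flow
equals `U·πR_i²` exactly. The experiment's inflow shape is not published;
the default ejects in 8 % of the cycle with a 30 % rise fraction. The short
piston-like stroke is deliberate: it is the only shape consistent with the
phantom's near-total pulse pressure (peak ≈ characteristic impedance × peak
flow), and it places the systolic peak during ejection so obstruction
effects can act on it.

## 1-D pulse-wave model

Cross-sectionally averaged mass and momentum balance on the tube,

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A_f)/∂x + (A_f/ρ)·∂p/∂x = −K(x)·8πν·Q/A_f

with the linear tube law `p = (A − A₀)/C_A`, `C_A = 2πR_i³/(E_s h)`, which
reproduces the Moens–Korteweg speed `c₀ = √(E_s h/(2ρR_i))` = 6.0 m/s for
the reference tube. A catheter is a rigid coaxial rod occupying
`[tip, outlet]`: there the fluid area is `A_f = A − πR_c²` and the Poiseuille
friction is multiplied by the annular-obstruction ratio

    K(k) = 1 / (1 − k⁴ − (1 − k²)²/ln(1/k)),    k = R_c/R_i,

the exact steady annular-Poiseuille result (≈ 3× at k = 0.3, ≈ 33× at
k = 0.7, 1.87 at the 6F ratio k = 0.125). The rod indicator is ramped over
two grid cells to avoid a grid-scale discontinuity at the tip.

**Afterload.** A Windkessel with peripheral resistance R_p, compliance C and
optionally a proximal resistance R_prox (three-element form). The default
experiment sets R_prox to the tube's characteristic impedance ρc₀/A₀ — the
standard absorbing termination in 1-D pulse-wave modelling. With a plain
two-element termination the outlet reflection coefficient is ≈ 0.95 and
every probe's systolic peak is a standing-wave superposition, which buries
mmHg-scale obstruction effects and corrupts foot detection; physically, the
rig's "resistance screw" is a localized resistive constriction, which the
proximal resistor represents. R_p and C are not published; the packaged
values (R_p = 3.514×10⁸ Pa·s/m³, C = 4.269×10⁻¹⁰ m³/Pa) are the output of
`tune_windkessel` — a bracketing bisection on R_p at fixed τ = R_p·C =
0.15 s — targeting the 106.4 mmHg uncatheterized peak at the tip probe,
frozen once. Note the tube's own volume compliance (C_A·L ≈ 4.5×10⁻⁹ m³/Pa)
dominates the lumped C, so the effective diastolic time constant is set by
R_p·C_A·L.

**Where the measured overestimation actually comes from.** Within the tube
itself, laminar annular resistance at k = 0.125 in an 8 mm bore contributes
only ~0.1 mmHg at the working flow — far too small to explain a double-digit
peak overestimation — and the first-passage systolic peak at the tip cannot
be influenced by resistance more than ~c·t_rise downstream anyway. Worse,
the junction's convective (venturi) pressure drop and the slightly slower
annular wave speed produce a small *negative* peak shift. The element that
makes the artifact self-contained is the outlet fitting: the catheter is
inserted from the distal end, so its body also occupies the narrow fitting
that couples the tube to the afterload. The model multiplies R_prox by
`K(R_c/r_fit)` with a default fitting bore r_fit = 4 mm. This is the
"same flow through a narrower duct downstream" mechanism lumped where the
duct is actually narrow; it elevates the baseline on which the systolic
spike rides, giving a peak overestimation that is strictly positive,
monotone in R_c, and (logarithmically slowly, a property of the annular
law) vanishing as R_c → 0. Setting `outlet_fitting_radius=None` recovers
the in-tube-annulus-only model.

**Numerics.** Explicit MacCormack (forward predictor / backward corrector)
on a uniform grid, dx = 2 mm, dt = 0.15 ms — the CFL bound
`dt ≤ dx/(c + |u|)` with c ≈ 6–7.5 m/s and |u| up to ~2 m/s is checked at
initialization and re-checked against the evolving state each step. A small
second-difference smoothing (coefficient 0.02) keeps the nonlinearly
steepening compression front monotone; the phantom's large pulse pressure
dilates the tube ~35 % in area at peak, so the front genuinely steepens over
round trips. Four cycles are simulated from rest and the last is reported
(the published protocol simulated three). Cycle volume bookkeeping
(trapezoidal inlet/outlet volumes and the stored-volume change) is carried
in the result; the residual stays below 1 % of stroke volume in the default
and catheterized configurations, and the tip peak changes by < 1 % when dx
and dt are halved. Catheter radii ≥ 1.5 mm against the 4 mm fitting drive
water-hammer transients outside the linear tube law's validity; the
stability guard rejects them, and the tested range stays clinical
(≤ 1.25 mm, i.e. ≤ 7.5F).

## Catheter-manometer dynamics

The fluid column is a second-order system:

    f_n = (1/2π)·√(πR²·(dP/dV)/(ρl)),    ζ = (4μl/R³)/√(ρlπ·(dP/dV)).

For the reference catheter, inverting the first relation at the measured
f_n = 40 Hz gives dP/dV = 1.568×10¹⁴ Pa/m³, and substituting that into the
second yields ζ = 0.156 — within 5 % of the measured 0.15, closing the
consistency triangle. The published relation between dP/dV and the catheter
wall modulus is implemented under its unique dimensionally consistent
grouping, `E_cath = (dP/dV)·2tV/(3πl)` with `V = πR²l` (a unit audit guards
the grouping, and the pair `compliance_from_modulus` /
`modulus_from_compliance` are exact inverses); however, with the stated
32 MPa modulus this relation implies dP/dV ≈ 7×10¹⁷ Pa/m³, three orders
above the value the measured f_n requires. The package therefore never
derives dynamics through the modulus route — everything is anchored on the
f_n/ζ formulas.

Distortion is applied in the time domain: `ÿ + 2ζω_n·ẏ + ω_n²y = ω_n²p(t)`
integrated by fixed-step RK4 at the waveform rate (sub-stepped whenever
`f_n·dt > 0.1`), starting at the first input sample with zero velocity. The
first ~2/(ζω_n) seconds are the settling transient; the pipeline distorts
periodic probe cycles by tiling two warm-up cycles and keeping the last, so
analyzed cycles are in filter steady state. The steady-state sinusoid gain
matches the analytic `|H(f)| = 1/√((1−r²)² + (2ζr)²)` within 2 % over two
decades (tested).

Two transducer configurations are carried through the comparison pipeline:
the nominal (f_n = 40 Hz, ζ = 0.15) and a degraded, air-bubble-like one
(f_n = 4 Hz, ζ = 0.8). The degraded column exists because a second-order
system at f_n = 40 Hz barely touches a 5.4 Hz component (|H| ≈ 1.02): the
strong in-vitro damping of the dicrotic ring and the 3.5× PWV inflation
reported for real fluid-filled catheters cannot be produced by the nominal
parameters, and the package demonstrates those phenomena with the degraded
configuration instead of pretending the nominal one explains them.

## Analysis conventions

**Features.** P_s/P_d are extrema over complete cycles (after an optional
transient exclusion). The dicrotic notch is the first local-minimum /
local-maximum pair after the systolic peak on a lightly smoothed
(Savitzky–Golay, ~50 ms window, cubic) copy, requiring ≥ 0.1 mmHg rebound.

**Foot and PWV.** The foot is the intersecting-tangents variant: the
horizontal line through the pre-upstroke minimum meets the tangent at the
steepest point of the upstroke, with the slope refined to sub-sample
precision by a quadratic fit to the discrete derivative. The slope search is
restricted to the rise toward the cycle's global maximum so later
(reflected, nonlinearly steepened) fronts are ignored. PWV over a separation
Δx averages Δx/Δt over all probe pairs at that separation (mean of ratios;
ratio of means is available — the published protocol does not say which it
used). A non-positive transit time is reported as an error, not a value.

**Spectra.** `amplitude_spectrum` removes the mean, optionally tapers
(Hann), zero-pads by the requested factor and reports the single-sided
amplitude spectrum normalized by the window's coherent gain; Parseval
consistency is carried in the result. The *ring* estimator deserves its own
convention: an exactly periodic record has spectral lines only at integer
multiples of the heart rate, so a 5.4 Hz interharmonic mode cannot appear as
a local maximum of the full-record transform — on real signals it does only
because beats decohere. `dicrotic_ring_spectrum` therefore isolates the mode
the way the eye does: it takes one designated steady cycle, keeps the
descending limb from the dicrotic dip onward, removes the exponential
diastolic trend, tapers and zero-pads. `secondary_peak` (largest local
maximum above a 3 Hz exclusion band, with an amplitude floor of 1 % of the
fundamental) applied to that spectrum recovers the generator's ring
frequency within ±0.05 Hz at the default operating point and tracks it
across 5–8 Hz; absence of a post-systolic dip returns "no ring", a valid
result for heavily damped traces.

**Curvature QC.** One cycle is normalized to the unit square (time and
amplitude each to [0, 1]); κ = |y″|/(1 + y′²)^{3/2} is computed by central
differences and integrated over the cycle; multi-cycle records report the
per-cycle mean. The published threshold 3.85 separates distorted from
control traces; the threshold's direction is not stated in the source, but
clean signals were reported at 6–8.7, so *below* threshold ⇒ distorted is
the implemented reading. The default synthetic waveform scores 7.3; heavy
low-pass distortion strictly reduces the score (both tested). The unit-square
normalization makes the statistic exactly invariant under affine amplitude
rescaling, and the exact normalization of the original method is not
restated in the source — this reconstruction keeps its published constant.

**Report.** `peak_overestimation_pct` compares the catheterized and
uncatheterized *simulations* at the tip probe — the numerical-model
comparison, which in the reference study also involved no fluid column (its
catheter was a rigid body). The transducer-distorted overestimation is
reported separately (`measured_peak_overestimation_pct`); on the sharp
phantom upstroke the underdamped nominal transducer adds substantial
resonance overshoot, and folding that into the headline number would
conflate two mechanisms. The catheter PWV column uses the degraded
transducer: the nominal one rings at 40 Hz on the steep upstroke, which
defeats foot detection, and the PWV inflation is a fluid-column effect in
any case.

## What the synthetic data does and does not show

The generator reproduces the *structural* features the analyses assume — a
periodic pulse with controlled extrema, a notch-generating interharmonic
ring, spectral fundamental at the heart rate — with no beat-to-beat
variability, baseline drift, or acquisition noise unless requested. Passing
tests therefore demonstrate that the algorithms recover known structure
exactly under clean conditions; they do not demonstrate robustness to the
nonstationarity of clinical recordings. Similarly, the 1-D surrogate
reproduces the direction and mechanism of the obstruction and
dynamic-response biases, not the published magnitudes: those depend on
unpublished afterload settings and on 3-D effects (tip vortices, eccentric
and moving catheters) explicitly outside this model, and the published
experimental values (24 % peak overestimation in vitro, PWV of 19 m/s from
catheter traces) are not desk-reproducible. Quantities that *are* anchored —
the dimensionless numbers, the f_n/ζ/dP/dV triangle, the annular-resistance
range, the radius ratios, the pulse-pressure ratio arithmetic, the 1 Hz /
5.4 Hz spectral pair — are recomputed by `scripts/acceptance.py`.

## Known limitations

- Linear tube law: adequate for wave-speed physics near the working point,
  but the phantom's 100 mmHg pulse dilates the tube far enough that the
  neglected strain-stiffening matters for absolute peaks, and extreme
  (≥ 7.5F) catheters against the default fitting produce transients the law
  cannot represent.
- Laminar, fully developed friction (Poiseuille/annular): at Womersley 20
  the oscillatory wall shear is substantially higher than Poiseuille's; the
  friction model is used for the resistance *ratio*, where the laminar form
  is the published analytic result, not for absolute viscous losses.
- The catheter is rigid, coaxial and stationary; the lumped fitting-blockage
  element stands in for the unmodelled distal plumbing, and its 4 mm bore is
  a modelling choice, not a measured dimension.
- The ring-frequency estimator assumes a single dominant damped mode on the
  diastolic limb; multiple overlapping modes would bias it.
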