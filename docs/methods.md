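# Methods

`optoclamp` simulates closed-loop control of the cardiac action potential
(AP) at a 1-kHz update rate. A feedback controller reads the membrane
potential V_m once per millisecond, compares it with a setpoint AP, and
actuates either an injected current (dynamic clamp) or one or two
light-gated membrane currents (optogenetics): a blue-light-gated
depolarizing conductance (CheRiff-like channel) and a red-light-driven
hyperpolarizing pump (Jaws-like). Everything runs against a synthetic
cardiomyocyte plant, so the whole control problem is simulated end to end
with no hardware and no external data.

## The synthetic plant

The plant is a phenomenological atrial-myocyte membrane in physical units
(mV, ms; currents as densities per capacitance, i.e. mV/ms):

    dV/dt = -( I_fast + I_slow + I_out(V) + I_blue + I_red - I_inj )

* `I_fast = h_f · m∞(V) / tau_in · (V - E_in)` — strong regenerative inward
  current driving the upstroke; its gate `h_f` inactivates within a few
  milliseconds of depolarization and only recovers well below threshold.
* `I_slow = g_si · h · p∞(V) · (V - E_in)` — weak plateau inward current;
  its gate `h` closes with `tau_close` and is therefore the AP-duration
  lever. Drug-like interventions multiply `tau_close` (`f_4AP = 1.55`
  prolongs, `f_cch = 0.10` shortens).
* `I_out(V)` — ungated outward current whose conductance is shaped in V:
  an inward-rectifier component (`1/tau_out`, strong near rest, off at the
  plateau), a small plateau component (`g_so`), and a mid-range component
  (`g_tail`, on between about −52 and −24 mV) that carries late
  repolarization. The split mirrors the textbook division of cardiac
  repolarizing currents (I_K1, plateau K⁺ current, I_Kur/I_to-like) and is
  what gives the light actuators realistic authority at the plateau while
  keeping rest stiff.
* `I_blue = g_blue · a_blue · (V - E_blue)` — the blue channel is a
  conductance shunting V toward its apparent reversal `E_blue = -11.2 mV`
  (the plateau potential measured under maximal 470-nm light); it can only
  depolarize while V is below `E_blue`.
* `I_red = I_red_max · a_red` — the red pump is voltage independent.
* Both actuator activations relax first order toward the commanded
  normalized irradiance (1.0 ≡ 1.5 mW/mm²) with `tau_act = 1.5 ms`, in the
  range of published fast-opsin on-kinetics.

Integration is explicit Euler at a 0.05-ms substep with zero-order hold of
light and current over each 1-ms control tick, matching the hard-real-time
structure of the loop. The state is `(V, h, h_f, a_blue, a_red)`.

### Calibration by construction

Two parameters are solved, not hand-set:

* `E_K` is chosen so the unforced resting fixed point sits exactly at
  `V_rest_target = -75 mV` (E_K enters the outward current linearly).
* `I_red_max` is chosen so a sustained maximal red drive holds V at
  −82 mV, the plateau measured for the red actuator in monolayers. A
  single-cell preset (`single_cell_params`) instead calibrates to a −25 mV
  shift from rest.

The remaining defaults were tuned once so that, at 1-Hz pacing, the plant
reproduces the study conditions: resting potential −75 mV, APD90
300 ± 2 ms, peak near +20 mV (electrical pacing; the optically paced peak
is lower because the blue pulse shunts V toward −11.2 mV, as in the real
preparation), a maximal blue plateau within 1 mV of −11.2 mV, a 4AP-like
model AP of ≈ 420 ms APD90 and a carbachol-like model of ≈ 96 ms. The
shape of the natural plateau (flat early phase, −11.2-mV crossing near
250 ms, fast tail) matters for enforcement of slowly repolarizing models:
above `E_blue` no actuator can depolarize, so there the cell itself must
carry the waveform.

What the plant does **not** emulate: ionic concentration dynamics, spatial
propagation and activation delays across a monolayer, opsin spectra and
desensitization, beat-to-beat biological variability, and electrode or
amplifier artifacts. Passing the accuracy thresholds here therefore shows
that the control algorithms and their tuning behave correctly against a
realistic single-compartment excitable load — not that any particular
biological preparation would yield the same numbers.

## The controllers

All controllers run once per 1-ms tick.

* **APqr** (adaptive proportional): error `e = V_m − AP_ideal[i]` against a
  setpoint logged as the element-wise mean of `lognum = 5` drug-free beats;
  output `I_out = (C_m / R_m) · e`. `R_m` is re-estimated every tick: an
  overshoot (error sign flip) multiplies `R_m` by `R_m_corr_up = 1.2`
  (gain down, fast), a diverging error divides it by `R_m_corr_down =
  1.01` (gain up, slow). The adaptation is bounded
  (`R_m ∈ [60, 10⁶]`): unbounded multiplicative adaptation eventually
  pushes any delayed loop through its stability limit. The `C_m/R_m` form
  is treated as a numeric gain heuristic, not a dimensional current law.
* **APqrPID**: `PID = K_P·e + K_I·e_sum + K_D·e_derivative` with the plain
  running sum `e_sum += e` and a derivative obtained by least-squares
  regression of the last `l = 10` errors against time (sign convention: a
  rising error gives a positive derivative). Defaults `K_P = 80`,
  `K_I = 3`, `K_D = 50` sit mid-range of the tuning intervals reported for
  this controller family. Anti-windup: the integral accumulation of a tick
  is reverted whenever the routed output is saturated — clipped at full
  drive, or gated off entirely — otherwise long enforced APs wind the sum
  far beyond anything the actuators can deliver.
* **Output routing**: positive PID (V_m too depolarized) drives the red
  LED, negative PID the blue LED, each as `min(scale·|PID|, 1)`; blue is
  permitted only while the *measured* V_m is below `V_plateau = -11.2 mV`.
  Exactly one channel is nonzero per tick.
* **APqrLE** (waveform enforcement): the PID core tracking a file-loaded or
  generated model AP. A 10-ms blue pacing pulse at the start of each 1-s
  cycle triggers the AP (pacing supersedes corrective output, and the
  integral is frozen there). The upstroke is detected as the first 1-ms
  dV/dt above 10 mV/ms — above the slow light-driven foot, so detection
  marks the regenerative phase — and the model is aligned to it by value:
  the model pointer starts at the first rising-limb sample that reaches
  the measured V_m. Between APs the model's resting potential is enforced.

### Output scale and stability

A single `scale` maps the dimensionless controller output to normalized
irradiance (or injected current density). The blue channel is intrinsically
"hot": near rest its driving force is ~65 mV, so a unit of blue drive moves
V an order of magnitude faster than a unit of red drive. The stable range
of `scale` is therefore set by the blue channel near rest, and the default
(`1/850` for the PID controllers) is the hottest setting at which the
dual-channel loop stays quiet in the worst region (the rectifier's
negative-slope zone around −50 to −60 mV). Like the laboratory practice
this emulates, the scale is tuned per experimental arrangement: the canned
recipes use 1.0 (current injection), 0.05 (single red LED) and 1/850
(dual optical); slow-ramp enforcement benefits from a slightly cooler
setting. The PID gains themselves are never changed between scenarios.

## The loop engine and protocols

Beats are stimulus-clocked (beat n = [n·1000 ms, (n+1)·1000 ms)), so
setpoint alignment needs no event detection. A restoration run executes
`lognum` drug-free logging beats, applies the drug-like perturbation, holds
a configurable pause (default 10 beats, standing in for "until drug effects
are evident"), then corrects live. The light-disturbance protocol adds a
preprogrammed 200-ms blue pulse (0.1 of 1.5 mW/mm²) 200 ms after the
stimulus on every 5th beat. Electrical pacing is a 5-ms, 15-mV/ms pulse;
optical pacing a 10-ms blue pulse at 0.5/1.5 normalized irradiance.
Enforcement runs begin with electrically paced, uncontrolled beats (the
endogenous reference), after which APqrLE paces optically and forces the
model. Every tick is logged (V_m, setpoint, error terms, output, both light
channels, injected current, phase, beat).

Drug model APs for enforcement are recorded from the drugged plant paced to
periodic steady state; models used by the optically paced enforcement
recipes are recorded under optical pacing so that the model's upstroke and
peak are reachable by the same actuators that must reproduce them.

## Quantification

AP timing is referenced to the earliest tick of maximal discrete upstroke
velocity. APD_x runs from there to the x% repolarization level
`V_peak − x·(V_peak − V_rest)` (V_rest = mean of the 50 ms before the
stimulus), with crossings linearly interpolated between samples — this
convention reproduces the closed-form APD90 values of the triangular
models (59.4 / 84 / 148 / 724 ms) to within one sample. V_m error is
measured minus reference, restricted to the window from dV/dt_max to
APD90 of the measured beat; the reference is the per-tick setpoint the
controller actually tracked, which keeps the comparison valid under
upstroke alignment. Error distributions use 5-mV bins centered on zero, so
the fraction within ±2.5 mV equals the center-bin mass exactly. Run-level
statistics pool all correction-window samples, skipping one (restoration)
or two (enforcement) settle-in beats.

## Problem sizes and determinism

Default runs are 25 beats (restoration: 5 logging + 10 paused + 10
correcting) and 10 beats (enforcement: 2 reference + 8 forced); drug models
are recorded to a 0.5-mV periodic steady state (typically 8–16 beats). With
`noise_sd = 0` (default) every run is exactly reproducible; optional
Gaussian measurement noise is seeded. A full scenario battery (all four
restoration scenarios, carbachol and four triangular enforcements)
completes in well under a minute on one CPU core.

## Known limitations

* The blue channel's conductance nature concentrates loop gain near rest;
  at the default scale small residual limit cycles can appear in the
  −50…−60 mV region during very slow forced ramps (visible as a few
  out-of-band samples late in t01 enforcement), and the slowest triangular
  ramp is reproduced best at a slightly cooler output scale.
* The fast triangular models (t13, t09) are tracked less tightly than in a
  low-conductance biological membrane, because the synthetic plant's
  plateau currents are comparatively stiff relative to the calibrated red
  pump; the pooled triangular-model accuracy is dominated by t01, as in the
  experimental precedent.
* Enforcement cannot exceed the blue actuator's plateau: model segments
  above −11.2 mV are carried by the plant's own plateau, so models whose
  early phase outlasts the natural plateau (e.g. a 4AP-like model forced
  onto a control cell) are reproduced less accurately in that zone.
* APD prolongation by the 4AP-like perturbation (~120 ms at APD90) was
  matched to the model-AP target (422 ms) rather than the single-cell
  prolongation statistics; both cannot be hit exactly with one scalar
  `tau_close` multiplier.
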