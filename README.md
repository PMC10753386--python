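# optoclamp

Closed-loop opto-electronic control of cardiac action-potential (AP)
morphology, simulated end to end.

In cardiomyocytes, abnormal AP shapes (e.g. drug- or disease-induced APD
prolongation) have real electrophysiological consequences, but classical
voltage clamp cannot impose waveforms on multicellular tissue. A feedback
loop that reads the membrane potential V_m at 1 kHz and answers with light
— driving a blue-light-gated depolarizing channel (CheRiff-like) and a
red-light-driven hyperpolarizing pump (Jaws-like) — can restore perturbed
AP shapes and even force arbitrary waveforms onto beating cells, without
any prior knowledge of the disturbance. `optoclamp` reimplements that
control system in software and pairs it with a calibrated synthetic
cardiomyocyte plant, so controllers, protocols and accuracy metrics can be
studied, tuned and tested with no hardware and no external data.

The package provides:

* **`optoclamp.plant`** — a phenomenological atrial-myocyte membrane
  (fast/slow inward currents, rectifier + plateau + mid-range outward
  currents) with CheRiff-like and Jaws-like photocurrents, calibrated so
  maximal blue/red illumination plateaus at −11.2 / −82 mV, rest sits at
  −75 mV, APD90 ≈ 300 ms at 1 Hz, and 4AP-like / carbachol-like
  perturbations give 420-ms / 96-ms model APs.
* **`optoclamp.controllers`** — the APqr controller family, one pure
  state-transition function per 1-ms tick:
  * APqr: adaptive proportional control, `I_out = (C_m/R_m)·e`, with
    per-tick re-estimation of `R_m` from overshoot / divergence of the
    error;
  * APqrPID: `PID = K_P·e + K_I·Σe + K_D·ê′`, the derivative `ê′`
    estimated by least-squares regression over the last `l` errors;
    positive output drives the red LED, negative the blue LED (gated off
    whenever V_m is above the blue channel's plateau potential);
  * APqrLE: the PID core tracking a file-loaded or generated model AP,
    with optical pacing and upstroke-aligned model indexing.
* **`optoclamp.loop_engine`** — the 1-kHz executor (logging → pause →
  correction; periodic light disturbances; electrical vs optical pacing)
  with complete per-tick logs.
* **`optoclamp.waveforms` / `optoclamp.metrics`** — triangular and
  drug-recorded model APs, model-AP CSV I/O, and all quantification
  (dV/dt_max, APD at arbitrary repolarization fractions, V_m-error traces
  and 5-mV-bin distributions).
* **`optoclamp` CLI** — canned recipes for every scenario.

## Worked example

Restore AP shape in the presence of a 4AP-like repolarization block using
both optogenetic actuators:

```console
$ optoclamp restore --recipe restore-dual-4ap --out results/demo
restore-dual-4ap: 100.0% of V_m-error samples within ±2.5 mV (median 0.09 mV)
```

The run logs five drug-free beats and averages them into the setpoint AP,
applies the 4AP-like perturbation (which alone prolongs APD90 from ~300 ms
to ~420 ms), waits ten beats, then corrects for ten beats. The printed
numbers summarize the correction windows (from the moment of maximal
upstroke velocity to 90% repolarization, settle-in beat excluded): every
1-ms error sample lies within ±2.5 mV of the setpoint, with a median
residual error of 0.09 mV — the controller holds the drugged cell on its
own drug-free waveform using red light alone. `results/demo/` contains the
full per-tick log (`loop_log.csv`), per-beat APD values (`metrics.json`)
and the fully resolved configuration (`config.yaml`).

Forcing a short, carbachol-like AP onto the unperturbed plant:

```console
$ optoclamp enforce --recipe enforce-carbachol --out results/demo-enforce
enforce-carbachol [carbachol]: 97.8% within ±2.5 mV
```

Other entry points: `optoclamp calibrate` (light-response protocol,
reports the plateau potential per channel), `optoclamp enforce --recipe
enforce-triangular` (the t13 → t09 → t05 → t01 → … series),
`optoclamp report` (error histograms and APD tables from saved logs), and
`optoclamp gen-waveforms` (writes the triangular model-AP CSV files).

The same functionality is available as a library:

```python
from optoclamp import (default_params, PidGains, run_enforcement,
                       named_triangular, control_error_stats)

log = run_enforcement(default_params(), PidGains(), named_triangular("t01"),
                      n_beats=8, ctl_beats=2)
print(control_error_stats(log, skip_beats=2).frac_within_2p5)
```

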