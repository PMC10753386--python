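"""Fixed-step 1-kHz closed-loop executor binding a controller to the plant.

The engine reproduces the experiment structure of the closed-loop studies:

* **Restoration** — the controller first *logs* a number of drug-free beats
  and averages them into its setpoint AP; the perturbation (drug-like
  parameter change and/or a periodic preprogrammed light pulse) is then
  applied; optionally the controller is *paused* for a number of beats while
  the perturbation develops; finally it *corrects* with live feedback.
* **Enforcement** — an initial electrically paced, uncontrolled segment
  registers the endogenous AP for comparison; electrical pacing then stops
  and APqrLE takes over, pacing optically and forcing the loaded model AP.

Beats are stimulus-clocked: beat n occupies [n*period, (n+1)*period) so the
setpoint needs no event detection for alignment.  Every tick is logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import controllers as ctl
from . import metrics
from .controllers import (ApqrGains, ControllerState, LEState, Phase,
                          PidGains, log_setpoint, revert_integral)
from .plant import (DARK, LightCommand, PlantParams, advance_tick,
                    apply_pharmacology, resting_state)
from .waveforms import SetpointAP

__all__ = [
    "Pacing",
    "Disturbance",
    "Protocol",
    "ControllerSpec",
    "LoopLog",
    "run_restoration",
    "run_enforcement",
    "write_log",
    "read_log",
    "control_error_stats",
]

LOG_COLUMNS = ["t", "beat", "phase", "V_m", "setpoint", "e", "e_sum",
               "e_derivative", "output", "blue", "red", "I_inj"]


@dataclass(frozen=True)
class Pacing:
    mode: Literal["electrical", "optical"] = "electrical"
    period_ms: int = 1000
    pulse_ms: int = 5               # 5-ms current pulse / 10-ms light pulse
    pulse_level: float = 15.0       # mV/ms (electrical) or irradiance (optical)

    def __post_init__(self) -> None:
        if self.period_ms <= self.pulse_ms:
            raise ValueError("pacing period must exceed the pulse duration")


OPTICAL_PACING = Pacing(mode="optical", pulse_ms=10, pulse_level=0.5 / 1.5)


@dataclass(frozen=True)
class Disturbance:
    """Preprogrammed blue light pulse perturbing every n-th beat."""

    every_n: int = 5
    delay_ms: int = 200
    duration_ms: int = 200
    blue_level: float = 0.1 / 1.5

    def __post_init__(self) -> None:
        if self.every_n < 1:
            raise ValueError("every_n must be >= 1")


@dataclass(frozen=True)
class Protocol:
    """Phase counts, pacing, perturbation and drug schedule of one run."""

    pacing: Pacing = field(default_factory=Pacing)
    disturbance: Disturbance | None = None
    drug: str = "none"
    logging_beats: int = 5
    paused_beats: int = 0
    correcting_beats: int = 10
    drug_onset_beat: int | None = None   # default: right after logging
    control: bool = True                 # False: perturbed run with output off

    def __post_init__(self) -> None:
        if self.disturbance is not None:
            d = self.disturbance
            if d.delay_ms + d.duration_ms >= self.pacing.period_ms:
                raise ValueError("disturbance must end within the pacing cycle")

    @property
    def onset(self) -> int:
        return self.logging_beats if self.drug_onset_beat is None else self.drug_onset_beat

    @property
    def total_beats(self) -> int:
        return self.logging_beats + self.paused_beats + self.correcting_beats

    def phase_of(self, beat: int) -> Phase:
        if beat < self.logging_beats:
            return Phase.LOGGING
        if beat < self.logging_beats + self.paused_beats:
            return Phase.PAUSED
        return Phase.CORRECTING


@dataclass(frozen=True)
class ControllerSpec:
    """Which algorithm drives the loop and how its output is actuated."""

    algorithm: Literal["apqr", "apqr_pid"] = "apqr_pid"
    gains: ApqrGains | PidGains = field(default_factory=PidGains)
    actuation: Literal["current", "single_optical", "dual_optical"] = "dual_optical"
    I_inj_limit: float = 50.0            # |current| clip, mV/ms (current mode)

    def __post_init__(self) -> None:
        if self.algorithm not in ("apqr", "apqr_pid"):
            raise ValueError(f"unknown control algorithm {self.algorithm!r}")
        if self.algorithm == "apqr" and not isinstance(self.gains, ApqrGains):
            raise ValueError("APqr requires ApqrGains")
        if self.algorithm == "apqr_pid" and not isinstance(self.gains, PidGains):
            raise ValueError("APqrPID requires PidGains")
        if self.algorithm == "apqr_pid" and self.actuation != "dual_optical":
            raise ValueError("APqrPID drives the dual optical actuators")


@dataclass
class LoopLog:
    """Per-tick record of a closed-loop run plus the setpoint it tracked."""

    frame: pd.DataFrame
    setpoint: SetpointAP | None = None
    period_ms: int = 1000

    def beat(self, n: int) -> pd.DataFrame:
        return self.frame[self.frame["beat"] == n]

    def beats_in_phase(self, phase: Phase) -> list[int]:
        sel = self.frame.loc[self.frame["phase"] == phase.value, "beat"]
        return sorted(sel.unique())

    def vm_of_beat(self, n: int) -> np.ndarray:
        return self.beat(n)["V_m"].to_numpy()


def _controller_route(spec: ControllerSpec, out: float, V_m: float,
                      ) -> tuple[LightCommand, float, bool]:
    """Map raw controller output to (light, injected current, saturated)."""
    g = spec.gains
    if spec.actuation == "current":
        I = -g.scale * out                      # positive error -> hyperpolarizing
        clipped = abs(I) > spec.I_inj_limit
        return DARK, max(-spec.I_inj_limit, min(spec.I_inj_limit, I)), clipped
    if spec.actuation == "single_optical":
        level = g.scale * out                   # red channel only
        return LightCommand(0.0, min(max(level, 0.0), 1.0)), 0.0, level > 1.0
    light, saturated = ctl.route_output(out, V_m, getattr(g, "V_plateau", -11.2),
                                        g.scale)
    return light, 0.0, saturated


def run_restoration(plant: PlantParams, controller: ControllerSpec,
                    protocol: Protocol, seed: int | None = None) -> LoopLog:
    """Execute a logging -> (pause) -> correction run and return the log."""
    if protocol.logging_beats != controller.gains.lognum:
        raise ValueError("protocol logging_beats must equal the controller lognum")
    period = protocol.pacing.period_ms
    rng = np.random.default_rng(plant.seed if seed is None else seed)

    params = plant
    state = resting_state(plant)
    cstate = ControllerState(phase=Phase.LOGGING)
    setpoint: SetpointAP | None = None
    logged: list[np.ndarray] = []
    rows = {c: [] for c in LOG_COLUMNS}
    t = 0.0

    for beat in range(protocol.total_beats):
        phase = protocol.phase_of(beat)
        cstate.transition(phase)
        if beat == protocol.onset:
            params = apply_pharmacology(params, protocol.drug)
        disturbed = (protocol.disturbance is not None
                     and beat >= protocol.logging_beats
                     and beat % protocol.disturbance.every_n == 0)
        beat_vm = np.empty(period)

        for i in range(period):
            V_meas = state.V
            if params.noise_sd > 0:
                V_meas += rng.normal(0.0, params.noise_sd)
            beat_vm[i] = V_meas

            pace_I, pace_blue = 0.0, 0.0
            if i < protocol.pacing.pulse_ms:
                if protocol.pacing.mode == "electrical":
                    pace_I = protocol.pacing.pulse_level
                else:
                    pace_blue = protocol.pacing.pulse_level
            dist_blue = 0.0
            if disturbed and protocol.disturbance.delay_ms <= i < (
                    protocol.disturbance.delay_ms + protocol.disturbance.duration_ms):
                dist_blue = protocol.disturbance.blue_level

            out = sp_val = err = 0.0
            light, I_ctrl = DARK, 0.0
            if phase is Phase.CORRECTING and setpoint is not None:
                sp_val = setpoint[i % len(setpoint)]
                if protocol.control:
                    if controller.algorithm == "apqr":
                        out, _ = ctl.apqr_tick(V_meas, cstate, setpoint,
                                               controller.gains)
                        light, I_ctrl, _ = _controller_route(controller, out, V_meas)
                    else:
                        out, _ = ctl.pid_tick(V_meas, cstate, setpoint,
                                              controller.gains)
                        light, I_ctrl, saturated = _controller_route(
                            controller, out, V_meas)
                        if saturated:
                            revert_integral(cstate)
                    err = cstate.e
                else:
                    err = V_meas - sp_val

            blue = min(1.0, pace_blue + dist_blue + light.blue)
            red = light.red
            I_inj = pace_I + I_ctrl
            state = advance_tick(state, params, LightCommand(blue, red), I_inj=I_inj)

            rows["t"].append(t)
            rows["beat"].append(beat)
            rows["phase"].append(phase.value)
            rows["V_m"].append(V_meas)
            rows["setpoint"].append(sp_val)
            rows["e"].append(err)
            rows["e_sum"].append(cstate.e_sum)
            rows["e_derivative"].append(cstate.e_derivative)
            rows["output"].append(out)
            rows["blue"].append(blue)
            rows["red"].append(red)
            rows["I_inj"].append(I_inj)
            t += 1.0

        if phase is Phase.LOGGING:
            logged.append(beat_vm)
            cstate.logged_beats += 1
            if cstate.logged_beats == controller.gains.lognum:
                setpoint = log_setpoint(logged, controller.gains.lognum)

    return LoopLog(frame=pd.DataFrame(rows), setpoint=setpoint, period_ms=period)


def run_enforcement(plant: PlantParams, gains: PidGains, model: SetpointAP,
                    n_beats: int = 10, ctl_beats: int = 3,
                    pacing: Pacing = OPTICAL_PACING,
                    ctl_pacing: Pacing | None = None,
                    seed: int | None = None) -> LoopLog:
    """Enforce a model AP with APqrLE after an uncontrolled reference segment.

    The first ``ctl_beats`` beats are paced electrically with no light
    output (phase LOGGING — the endogenous registration segment); APqrLE
    then paces optically and corrects against ``model`` for ``n_beats``
    beats (phase CORRECTING).
    """
    if ctl_pacing is None:
        ctl_pacing = Pacing()
    period = pacing.period_ms
    rng = np.random.default_rng(plant.seed if seed is None else seed)
    state = resting_state(plant)
    le = LEState()
    rows = {c: [] for c in LOG_COLUMNS}
    t = 0.0

    for beat in range(ctl_beats + n_beats):
        enforcing = beat >= ctl_beats
        phase = Phase.CORRECTING if enforcing else Phase.LOGGING
        for i in range(period):
            V_meas = state.V
            if plant.noise_sd > 0:
                V_meas += rng.normal(0.0, plant.noise_sd)

            out = sp_val = err = 0.0
            blue = red = I_inj = 0.0
            if enforcing:
                t_le = t - ctl_beats * period
                light, out, sp_val, _ = ctl.le_tick(
                    t_le, V_meas, le, model, gains, period_ms=period,
                    pace_ms=pacing.pulse_ms, pace_level=pacing.pulse_level)
                err = le.pid.e
                blue, red = light.blue, light.red
            else:
                if i < ctl_pacing.pulse_ms:
                    I_inj = ctl_pacing.pulse_level

            state = advance_tick(state, plant, LightCommand(blue, red), I_inj=I_inj)

            rows["t"].append(t)
            rows["beat"].append(beat)
            rows["phase"].append(phase.value)
            rows["V_m"].append(V_meas)
            rows["setpoint"].append(sp_val)
            rows["e"].append(err)
            rows["e_sum"].append(le.pid.e_sum)
            rows["e_derivative"].append(le.pid.e_derivative)
            rows["output"].append(out)
            rows["blue"].append(blue)
            rows["red"].append(red)
            rows["I_inj"].append(I_inj)
            t += 1.0

    return LoopLog(frame=pd.DataFrame(rows), setpoint=model, period_ms=period)


# -- log I/O -----------------------------------------------------------------

def write_log(log: LoopLog, path) -> None:
    """Write the per-tick log as CSV with a fixed column order."""
    log.frame.to_csv(path, index=False, columns=LOG_COLUMNS)


def read_log(path, setpoint: SetpointAP | None = None,
             period_ms: int = 1000) -> LoopLog:
    frame = pd.read_csv(path)
    if list(frame.columns) != LOG_COLUMNS:
        raise ValueError(f"{path}: unexpected log columns {list(frame.columns)}")
    return LoopLog(frame=frame, setpoint=setpoint, period_ms=period_ms)


# -- run-level statistics ----------------------------------------------------

def control_error_stats(log: LoopLog, beats: list[int] | None = None,
                        skip_beats: int = 0) -> metrics.ErrorStats:
    """V_m-error statistics over the correction windows of a run.

    For every correcting beat (optionally skipping the first ``skip_beats``
    settle-in beats), the per-tick error of the measured beat against the
    reference value the controller tracked at that tick is restricted to the
    beat's dV/dt_max -> APD_90 window; all samples are pooled into one
    distribution.  Using the tick-wise reference keeps the comparison valid
    when the controller aligns the model to the detected upstroke.
    """
    if beats is None:
        beats = log.beats_in_phase(Phase.CORRECTING)[skip_beats:]
    if not beats:
        raise ValueError("no correcting beats in this log")
    pooled = []
    for b in beats:
        f = log.beat(b)
        v = f["V_m"].to_numpy()
        e = v - f["setpoint"].to_numpy()
        m = metrics.ap_metrics(v, fractions=(0.9,))
        if 0.9 not in m.APD:
            raise ValueError(f"APD_90 undefined on beat {b}; window undefined")
        i0 = round(m.t_dvdt_max)
        i1 = round(m.t_repol[0.9])
        pooled.append(e[i0:i1 + 1])
    return metrics.error_stats(np.concatenate(pooled))
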