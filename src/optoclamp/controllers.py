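"""Tick-level closed-loop controllers: APqr, APqrPID and APqrLE.

All three controllers run once per 1-ms control tick on the live membrane
potential V_m and a setpoint AP (one pacing cycle of reference values):

* **APqr** — adaptive proportional control.  The error is
  ``e = V_m - AP_ideal[i]``; the output is ``I_out = K_P * e`` with
  ``K_P = C_m / R_m``, and ``R_m`` is re-estimated every tick: it is
  multiplied by ``R_m_corr_up`` when V_m overshoots the setpoint (the error
  changes sign, so the gain shrinks) and divided by ``R_m_corr_down`` when
  V_m moves away from it (the error grows without changing sign, so the
  gain rises).  ``K_P`` is treated as a numeric gain heuristic, not a
  dimensional current law; a single ``scale`` maps the output to normalized
  irradiance or injected current density.

* **APqrPID** — proportional-integral-derivative control with a plain
  running error sum (``e_sum += e`` each tick) and a derivative obtained by
  least-squares regression of the last ``l`` errors against time, which
  filters the single-step difference.  The signed PID value drives two
  antagonistic light channels: positive values (V_m too depolarized) command
  the red, hyperpolarizing LED; negative values command the blue,
  depolarizing LED, but only while V_m is below the blue actuator's plateau
  potential ``V_plateau`` — above it the channel cannot depolarize, so its
  output is gated off.

* **APqrLE** — the PID core driven by a file-loaded or generated model AP
  instead of a logged one, plus optical pacing: a 10-ms blue pulse at the
  start of each 1-s cycle triggers the AP, correction starts at the first
  detected upstroke and the model is aligned to it; between APs the model's
  resting potential is enforced.

Anti-windup: the integral is frozen on any tick whose routed output is
saturated (clipped at full drive, or gated to zero by the ``V_plateau``
rule); without this, long model APs wind the sum up far beyond anything the
actuators can deliver.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .plant import LightCommand
from .waveforms import SetpointAP

__all__ = [
    "Phase",
    "ApqrGains",
    "PidGains",
    "ControllerState",
    "log_setpoint",
    "apqr_tick",
    "regress_slope",
    "pid_tick",
    "route_output",
    "le_tick",
    "LEState",
]


class Phase(Enum):
    LOGGING = "logging"
    PAUSED = "paused"
    CORRECTING = "correcting"


_ALLOWED_TRANSITIONS = {
    (Phase.LOGGING, Phase.PAUSED),
    (Phase.LOGGING, Phase.CORRECTING),
    (Phase.PAUSED, Phase.CORRECTING),
}


@dataclass(frozen=True)
class ApqrGains:
    """Gains of the adaptive proportional controller."""

    C_m: float = 100.0          # pF
    R_m: float = 150.0          # initial adaptive gain denominator
    R_m_corr_up: float = 1.2    # multiplies R_m on overshoot (gain down, fast)
    R_m_corr_down: float = 1.01 # divides R_m when error diverges (gain up, slow)
    R_m_min: float = 60.0       # adaptation bounds: keep the loop gain finite
    R_m_max: float = 1e6        # and the controller responsive
    lognum: int = 5             # beats averaged into the setpoint
    scale: float = 1.0          # maps I_out to irradiance or current density

    def __post_init__(self) -> None:
        if self.R_m <= 0:
            raise ValueError("R_m must be positive")
        if self.R_m_corr_up <= 1.0 or self.R_m_corr_down <= 1.0:
            raise ValueError("correction factors must exceed 1")
        if not (0 < self.R_m_min <= self.R_m <= self.R_m_max):
            raise ValueError("need 0 < R_m_min <= R_m <= R_m_max")
        if self.lognum < 1:
            raise ValueError("lognum must be a positive integer")


@dataclass(frozen=True)
class PidGains:
    """Gains of the PID controllers (APqrPID, APqrLE)."""

    K_P: float = 80.0
    K_I: float = 3.0
    K_D: float = 50.0
    l: int = 10                 # regression window length (ticks)
    dt: float = 1.0             # ms, the control step
    V_plateau: float = -11.2    # mV; blue output allowed only below this
    lognum: int = 5
    scale: float = 1.0 / 850.0  # maps PID to normalized irradiance

    def __post_init__(self) -> None:
        if self.l < 2:
            raise ValueError("regression window needs l >= 2")
        if min(self.K_P, self.K_I, self.K_D) < 0:
            raise ValueError("gains must be non-negative")
        if self.lognum < 1:
            raise ValueError("lognum must be a positive integer")


@dataclass
class ControllerState:
    """Running controller memory."""

    phase: Phase = Phase.LOGGING
    i: int = 0                       # tick index within the pacing cycle
    e: float = 0.0                   # last error (mV)
    e_sum: float = 0.0               # integral accumulator (mV * ticks)
    e_derivative: float = 0.0        # last regression slope (mV/ms)
    e_window: deque = field(default_factory=lambda: deque(maxlen=10))
    R_m_current: float = math.nan    # adaptive value (APqr only)
    logged_beats: int = 0

    def transition(self, new: Phase) -> None:
        if new is self.phase:
            return
        if (self.phase, new) not in _ALLOWED_TRANSITIONS:
            raise ValueError(f"illegal phase transition {self.phase} -> {new}")
        self.phase = new


# -- setpoint logging --------------------------------------------------------

def log_setpoint(beats: Sequence[Sequence[float]], lognum: int) -> SetpointAP:
    """Average ``lognum`` aligned per-cycle V_m traces into the setpoint AP.

    The beats must all start at the pacing stimulus tick and share one
    length; the setpoint is their element-wise mean.
    """
    if len(beats) != lognum:
        raise ValueError(f"expected exactly lognum={lognum} beats, got {len(beats)}")
    arrs = [np.asarray(b, dtype=float) for b in beats]
    if len({a.shape for a in arrs}) != 1 or arrs[0].ndim != 1:
        raise ValueError("all logged beats must be 1-D and of equal length")
    return SetpointAP(values=np.mean(arrs, axis=0), origin="logged")


# -- APqr --------------------------------------------------------------------

def apqr_tick(V_m: float, state: ControllerState, setpoint: SetpointAP,
              gains: ApqrGains) -> tuple[float, ControllerState]:
    """One adaptive-proportional control step; returns (I_out, state).

    The state is updated in place and also returned.  After computing the
    output, R_m is re-estimated from the overshoot / moving-away predicates
    on (e, previous e) and the cycle index advances modulo the cycle length.
    """
    if state.phase is not Phase.CORRECTING:
        raise ValueError("apqr_tick requires the CORRECTING phase")
    if math.isnan(state.R_m_current):
        state.R_m_current = gains.R_m
    e_prev = state.e
    e = V_m - setpoint[state.i % len(setpoint)]
    I_out = (gains.C_m / state.R_m_current) * e

    overshoot = _sign(e) != _sign(e_prev) and abs(e_prev) > 0.0
    moves_away = (not overshoot) and abs(e) > abs(e_prev) and _sign(e) == _sign(e_prev)
    if overshoot:
        state.R_m_current *= gains.R_m_corr_up
    elif moves_away:
        state.R_m_current /= gains.R_m_corr_down
    state.R_m_current = min(gains.R_m_max, max(gains.R_m_min, state.R_m_current))
    if state.R_m_current <= 0 or not math.isfinite(state.R_m_current):
        raise FloatingPointError(f"adaptive R_m left (0, inf): {state.R_m_current}")

    state.e = e
    state.i = (state.i + 1) % len(setpoint)
    return I_out, state


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


# -- PID core ----------------------------------------------------------------

def regress_slope(e_window: Sequence[float], dt: float = 1.0) -> float:
    """Least-squares slope (mV/ms) of the error trajectory over a window.

    ``e_window`` holds the last ``l`` errors in chronological order (oldest
    first).  The closed form regresses the backward-indexed samples e[-j]
    against the sample age j*dt; the sign is flipped so that an error rising
    in time yields a positive slope.
    """
    l = len(e_window)
    if l < 2:
        raise ValueError("regression window needs at least 2 samples")
    sx = sy = sxy = sxx = 0.0
    for j in range(l):           # j = sample age in ticks; y = e[-j]
        x = j * dt
        y = e_window[l - 1 - j]
        sx += x
        sy += y
        sxy += x * y
        sxx += x * x
    slope_vs_age = (l * sxy - sx * sy) / (l * sxx - sx * sx)
    return -slope_vs_age


def pid_tick(V_m: float, state: ControllerState, setpoint: SetpointAP,
             gains: PidGains, setpoint_value: float | None = None,
             ) -> tuple[float, ControllerState]:
    """One PID control step; returns (PID value, state).

    ``setpoint_value`` overrides the indexed setpoint sample (used by APqrLE
    for resting-potential enforcement between APs).  The integral is
    accumulated here unconditionally; callers implementing anti-windup
    revert it via ``revert_integral`` when the routed output saturates.
    The cycle index advances modulo the cycle length.
    """
    if state.phase is not Phase.CORRECTING:
        raise ValueError("pid_tick requires the CORRECTING phase")
    sp = setpoint[state.i % len(setpoint)] if setpoint_value is None else setpoint_value
    e = V_m - sp
    state.e = e
    state.e_sum += e
    if state.e_window.maxlen != gains.l:
        state.e_window = deque(state.e_window, maxlen=gains.l)
    state.e_window.append(e)
    if len(state.e_window) == gains.l:
        e_derivative = regress_slope(state.e_window, gains.dt)
    else:
        e_derivative = 0.0       # warm-up until the window is full
    state.e_derivative = e_derivative
    pid = gains.K_P * e + gains.K_I * state.e_sum + gains.K_D * e_derivative
    if not math.isfinite(pid):
        raise FloatingPointError(f"PID output became non-finite (e={e}, "
                                 f"e_sum={state.e_sum}, e_der={e_derivative})")
    state.i = (state.i + 1) % len(setpoint)
    return pid, state


def revert_integral(state: ControllerState) -> None:
    """Anti-windup: undo the integral accumulation of the last tick."""
    state.e_sum -= state.e


def route_output(pid: float, V_m: float, V_plateau: float,
                 scale: float = 1.0) -> tuple[LightCommand, bool]:
    """Map a signed PID value onto the two LED channels.

    Positive PID (V_m above setpoint) drives the red, hyperpolarizing LED;
    negative PID drives the blue, depolarizing LED, but only while V_m is
    more negative than the blue actuator's plateau potential.  Returns the
    light command and a flag marking saturation (level clipped at 1, or blue
    demanded but gated off).
    """
    if pid > 0.0:
        level = scale * pid
        return LightCommand(0.0, min(level, 1.0)), level > 1.0
    if pid < 0.0:
        if V_m >= V_plateau:
            return LightCommand(0.0, 0.0), True   # gated: demand unmet
        level = scale * (-pid)
        return LightCommand(min(level, 1.0), 0.0), level > 1.0
    return LightCommand(0.0, 0.0), False


# -- APqrLE ------------------------------------------------------------------

@dataclass
class LEState:
    """APqrLE memory on top of the PID controller state."""

    pid: ControllerState = field(
        default_factory=lambda: ControllerState(phase=Phase.CORRECTING))
    V_prev: float = math.nan         # last measured V_m (for upstroke detection)
    model_index: int | None = None   # pointer into the model AP, None between APs
    model_upstroke: int | None = None
    armed: bool = True               # upstroke detector armed once per cycle

    def detect_upstroke(self, V_m: float, threshold: float = 10.0) -> bool:
        """1-ms discrete dV/dt exceeding ``threshold`` mV/ms.

        The threshold sits above the slow light-driven foot of the optically
        paced AP, so detection marks the regenerative phase of the upstroke
        and the model alignment matches the steep segments of both.
        """
        up = (not math.isnan(self.V_prev)) and (V_m - self.V_prev) > threshold
        return up


def _model_upstroke_index(model: SetpointAP) -> int:
    """Tick of maximal discrete upstroke velocity of the model (earliest)."""
    return int(np.argmax(np.diff(model.values)))


def _align_model_to_upstroke(model: SetpointAP, upstroke: int, V_m: float) -> int:
    """Index at which to start tracking the model after upstroke detection.

    The measured upstroke is typically steeper or shallower than the model's,
    so aligning by phase marker alone leaves a large transient error.  Instead
    the pointer is placed at the first model sample on the rising limb whose
    value reaches the currently measured V_m (capped at the model peak), so
    the two trajectories meet where they cross.
    """
    v = model.values
    i_peak = upstroke + int(np.argmax(v[upstroke:upstroke + 50]))
    for i in range(upstroke, i_peak + 1):
        if v[i] >= V_m:
            return i
    return i_peak


def le_tick(t: float, V_m: float, state: LEState, model: SetpointAP,
            gains: PidGains, period_ms: int = 1000, pace_ms: int = 10,
            pace_level: float = 0.5 / 1.5,
            ) -> tuple[LightCommand, float, float, LEState]:
    """One APqrLE step; returns (light, PID value, setpoint used, state).

    During the first ``pace_ms`` of each cycle a fixed blue pacing pulse is
    emitted, superseding corrective output (the integral is frozen there).
    Once an upstroke is detected the model is aligned to it — its own
    upstroke sample is matched to the detected tick — and PID correction
    tracks the model sample-by-sample; after the model cycle ends, and before
    the next upstroke, the model's resting potential is enforced.
    """
    if model.origin not in ("file", "generator"):
        raise ValueError("APqrLE requires a file-loaded or generated model AP")
    if len(model) < period_ms:
        raise ValueError(f"model ({len(model)} ticks) shorter than the "
                         f"{period_ms}-ms pacing cycle")
    if state.model_upstroke is None:
        state.model_upstroke = _model_upstroke_index(model)

    tick_in_cycle = int(round(t)) % period_ms
    pacing = tick_in_cycle < pace_ms
    if tick_in_cycle == 0:
        state.armed = True                        # one alignment per cycle

    if state.armed and state.detect_upstroke(V_m):
        state.model_index = _align_model_to_upstroke(model, state.model_upstroke,
                                                     V_m)
        state.armed = False
    state.V_prev = V_m

    if state.model_index is not None and state.model_index < len(model):
        sp = model[state.model_index]
        state.model_index += 1
    else:
        sp = model.V_rest                          # between APs: enforce rest

    pid, _ = pid_tick(V_m, state.pid, model, gains, setpoint_value=sp)
    light, saturated = route_output(pid, V_m, gains.V_plateau, gains.scale)
    if pacing:
        revert_integral(state.pid)                 # output superseded: freeze I
        return LightCommand(pace_level, 0.0), pid, sp, state
    if saturated:
        revert_integral(state.pid)
    return light, pid, sp, state
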