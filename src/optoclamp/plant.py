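"""Synthetic optogenetic cardiomyocyte plant.

A phenomenological stand-in for a paced atrial-myocyte monolayer expressing a
blue-light-gated depolarizing channel (CheRiff-like) and a red-light-driven
hyperpolarizing pump (Jaws-like).  The endogenous membrane is a two-current
excitable model in physical units:

    dV/dt = -(I_in(V, h) + I_out(V) + I_blue + I_red - I_inj)      [mV/ms]

* ``I_in``  — regenerative inward current, gated by the recovery variable
  ``h`` and an instantaneous activation sigmoid; reverses at
  ``V_rest_target + amplitude`` so the AP peak lands near +20 mV.
* ``I_out`` — ungated outward current with a voltage-shaped conductance:
  an inwardly-rectifying component (strong near rest, off at plateau) plus a
  small plateau component.  This separation is what gives light actuators
  realistic authority during the plateau while keeping the resting potential
  stiff.
* ``h``     — single recovery gate: closes with ``tau_close`` above the gate
  voltage, reopens with ``tau_open`` below it.  Drug-like interventions scale
  ``tau_close`` (a 4AP-like block prolongs the AP, a carbachol-like current
  shortens it).

Currents are densities (per capacitance, i.e. mV/ms), so no cell-size choice
is needed.  All rate constants are in ms, voltages in mV.

The two photocurrents follow the field's standard idealizations: the blue
channel is a conductance shunting V toward its apparent reversal
(``E_blue``, the plateau potential reached under maximal 470-nm light), and
the red pump is a voltage-independent outward current proportional to drive.
Both actuators relax first-order toward the commanded normalized irradiance
(1.0 = maximal intensity, 1.5 mW/mm^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

__all__ = [
    "PlantParams",
    "PlantState",
    "LightCommand",
    "DARK",
    "default_params",
    "single_cell_params",
    "resting_state",
    "blue_current",
    "red_current",
    "endogenous_current",
    "step_plant",
    "advance_tick",
    "apply_pharmacology",
    "DRUG_LABELS",
]

# -- fixed structural constants of the endogenous model ----------------------
# Activation midpoints/slopes (mV).  These shape the excitability and the
# rectification and are not experiment-level tunables.
_M_HALF = -35.0   # fast inward activation midpoint (upstroke)
_M_SLOPE = 6.0
_P_HALF = -25.0   # slow (plateau) inward activation midpoint
_P_SLOPE = 6.0
_R_HALF = -65.0   # inward-rectifier deactivation midpoint
_R_SLOPE = 6.5
_S_HALF = -30.0   # plateau outward activation midpoint
_S_SLOPE = 6.0
_T_LOW = -56.0    # mid-range (tail) outward current window, lower edge
_T_HIGH = -20.0   # upper edge
_T_SLOPE = 4.0
_V_GATE = -60.0   # slow recovery-gate switching voltage
_V_GATE_FAST = -65.0   # fast-gate switching voltage
_TAU_FAST_CLOSE = 4.0  # ms; fast inward inactivation at depolarized V
_TAU_FAST_OPEN = 60.0  # ms; fast inward recovery near rest


def _sig(x: float) -> float:
    """Logistic function with overflow guard."""
    if x > 35.0:
        return 1.0
    if x < -35.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class LightCommand:
    """Normalized irradiance commands for the two LED channels.

    1.0 corresponds to maximal intensity (1.5 mW/mm^2).  When produced by the
    controller output router at most one channel is nonzero.
    """

    blue: float = 0.0
    red: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.blue <= 1.0 and 0.0 <= self.red <= 1.0):
            raise ValueError(
                f"light levels must be in [0, 1]; got blue={self.blue}, red={self.red}"
            )


DARK = LightCommand(0.0, 0.0)


@dataclass(frozen=True)
class PlantParams:
    """Parameters of the synthetic monolayer.

    Defaults are calibrated (see ``default_params``) so that, at 1-Hz pacing,
    the resting potential is -75 mV, APD90 is ~300 ms, a 1-s maximal blue
    pulse plateaus at -11.2 mV and a 1-s maximal red pulse plateaus at
    -82 mV.
    """

    V_rest_target: float = -75.0   # mV
    amplitude: float = 95.0        # mV; inward reversal = V_rest_target + amplitude
    tau_in: float = 0.5            # ms; inverse strength of the fast inward current
    tau_out: float = 1.1           # ms; 1/tau_out = rectifier conductance (per C)
    tau_open: float = 100.0        # ms; recovery-gate reopening
    tau_close: float = 120.0       # ms; recovery-gate closing (APD lever)
    g_si: float = 0.128            # slow (plateau) inward conductance (per C, 1/ms)
    g_so: float = 0.009            # plateau outward conductance (per C, 1/ms)
    g_tail: float = 0.02           # mid-range repolarizing conductance (per C, 1/ms)
    g_blue: float = 0.85           # max light-gated conductance (per C, 1/ms)
    E_blue: float = -11.2          # mV; apparent reversal of the blue actuator
    I_red_max: float = math.nan    # mV/ms; max red pump density; solved if NaN
                                   # so maximal red drive plateaus at -82 mV
    tau_act_blue: float = 1.5      # ms; actuator on/off kinetics (fast opsins)
    tau_act_red: float = 1.5       # ms
    f_4AP: float = 1.54            # tau_close multiplier of the 4AP-like block
    f_cch: float = 0.10            # tau_close multiplier of the carbachol-like current
    C_m: float = 100.0             # pF; bookkeeping for the controller gain heuristic
    noise_sd: float = 0.0          # mV; optional measurement noise
    seed: int = 0
    E_K: float = field(default=math.nan)  # mV; outward reversal, solved if NaN

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close",
                     "tau_act_blue", "tau_act_red"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.f_cch <= 1.0 <= self.f_4AP):
            raise ValueError("need 0 < f_cch <= 1 <= f_4AP")
        if self.E_blue <= self.V_rest_target:
            raise ValueError("E_blue must be above V_rest_target (depolarizing actuator)")
        if math.isnan(self.E_K):
            object.__setattr__(self, "E_K", _solve_E_K(self))
        if math.isnan(self.I_red_max):
            object.__setattr__(self, "I_red_max", _solve_I_red_max(self))

    # -- derived quantities --------------------------------------------------
    @property
    def E_in(self) -> float:
        return self.V_rest_target + self.amplitude


def _inward(p: PlantParams, V: float, h: float, h_f: float) -> float:
    """Total gated inward current density (negative = depolarizing).

    Fast component (upstroke): strong, inactivates within a few ms.
    Slow component (plateau): weak, inactivates with tau_close and therefore
    sets the AP duration.
    """
    fast = (h_f * _sig((V - _M_HALF) / _M_SLOPE) / p.tau_in) * (V - p.E_in)
    slow = p.g_si * h * _sig((V - _P_HALF) / _P_SLOPE) * (V - p.E_in)
    return fast + slow


def _outward_conductance(p: PlantParams, V: float) -> float:
    tail = _sig((V - _T_LOW) / _T_SLOPE) * _sig(-(V - _T_HIGH) / _T_SLOPE)
    return (_sig(-(V - _R_HALF) / _R_SLOPE) / p.tau_out
            + p.g_so * _sig((V - _S_HALF) / _S_SLOPE)
            + p.g_tail * tail)


def _outward(p: PlantParams, V: float) -> float:
    return _outward_conductance(p, V) * (V - p.E_K)


def _solve_E_K(p: PlantParams) -> float:
    """Choose E_K so the unforced resting fixed point sits at V_rest_target.

    E_K enters the outward current linearly, so the balance
    I_in(V_rest, 1, 1) + G_out(V_rest) * (V_rest - E_K) = 0 is solved
    directly.
    """
    V = p.V_rest_target
    return V + _inward(p, V, 1.0, 1.0) / _outward_conductance(p, V)


def _solve_I_red_max(p: PlantParams, V_plateau_red: float = -82.0) -> float:
    """Red-pump density such that maximal red drive holds V at the target
    hyperpolarized plateau (with the recovery gate open)."""
    return -endogenous_current(p, V_plateau_red, 1.0)


def default_params(**overrides) -> PlantParams:
    """Calibrated default plant.

    ``I_red_max`` is solved so a sustained maximal red drive plateaus at
    -82 mV; ``E_K`` is solved in ``PlantParams`` so rest sits at
    ``V_rest_target``.  Overrides are applied before calibration.

    ``red_plateau`` may be overridden to use the single-cell calibration
    (a -25 mV shift from rest, i.e. plateau at -100 mV) instead of the
    monolayer value.
    """
    red_plateau = overrides.pop("red_plateau", -82.0)
    base = PlantParams(**overrides)
    if "I_red_max" not in overrides:
        base = replace(base, I_red_max=_solve_I_red_max(base, red_plateau))
    return base


def single_cell_params(**overrides) -> PlantParams:
    """Alternative preset: red actuator calibrated to the single-cell
    measurement (maximal red shifts V_m by -25 mV from rest)."""
    overrides.setdefault("red_plateau", -100.0)
    return default_params(**overrides)


@dataclass
class PlantState:
    """Instantaneous state of the plant."""

    V: float            # mV
    h: float            # slow recovery gate, [0, 1]
    a_blue: float       # actuator activations, [0, 1]
    a_red: float
    t: float = 0.0      # ms
    h_fast: float = 1.0 # fast recovery gate, [0, 1]

    def copy(self) -> "PlantState":
        return PlantState(self.V, self.h, self.a_blue, self.a_red, self.t,
                          self.h_fast)


def resting_state(params: PlantParams) -> PlantState:
    """Exact unforced fixed point (rest, gates open, actuators dark)."""
    return PlantState(V=params.V_rest_target, h=1.0, a_blue=0.0, a_red=0.0,
                      t=0.0, h_fast=1.0)


# -- currents ----------------------------------------------------------------

def blue_current(V: float, a_blue: float, params: PlantParams) -> float:
    """Blue-channel photocurrent density g_blue * a * (V - E_blue).

    Negative (inward, depolarizing) iff V < E_blue; zero in the dark.
    """
    if not 0.0 <= a_blue <= 1.0:
        raise ValueError("a_blue must be in [0, 1]")
    return params.g_blue * a_blue * (V - params.E_blue)


def red_current(a_red: float, params: PlantParams) -> float:
    """Red-pump photocurrent density I_red_max * a (outward, V-independent)."""
    if not 0.0 <= a_red <= 1.0:
        raise ValueError("a_red must be in [0, 1]")
    return params.I_red_max * a_red


def endogenous_current(params: PlantParams, V: float, h: float,
                       h_fast: float = 1.0) -> float:
    """Total endogenous current density at (V, h, h_fast)."""
    return _inward(params, V, h, h_fast) + _outward(params, V)


# -- integration -------------------------------------------------------------

def step_plant(state: PlantState, params: PlantParams, light: LightCommand,
               I_inj: float = 0.0, dt_sub: float = 0.05) -> PlantState:
    """Advance the plant by one explicit Euler substep.

    ``light`` and ``I_inj`` are held constant across the substep (zero-order
    hold is applied at the 1-ms control tick by the caller).
    """
    if dt_sub > 0.1:
        raise ValueError("dt_sub must be <= 0.1 ms")
    s = state.copy()
    _substep(s, params, light.blue, light.red, I_inj, dt_sub)
    _check_finite(s)
    return s


def _substep(s: PlantState, p: PlantParams, blue: float, red: float,
             I_inj: float, dt: float) -> None:
    V, h, h_f = s.V, s.h, s.h_fast
    I = (_inward(p, V, h, h_f) + _outward(p, V)
         + p.g_blue * s.a_blue * (V - p.E_blue)
         + p.I_red_max * s.a_red
         - I_inj)
    s.V = V - dt * I
    if V >= _V_GATE:
        h -= dt * h / p.tau_close
    else:
        h += dt * (1.0 - h) / p.tau_open
    s.h = min(1.0, max(0.0, h))
    if V >= _V_GATE_FAST:
        h_f -= dt * h_f / _TAU_FAST_CLOSE
    else:
        h_f += dt * (1.0 - h_f) / _TAU_FAST_OPEN
    s.h_fast = min(1.0, max(0.0, h_f))
    s.a_blue = min(1.0, max(0.0, s.a_blue + dt * (blue - s.a_blue) / p.tau_act_blue))
    s.a_red = min(1.0, max(0.0, s.a_red + dt * (red - s.a_red) / p.tau_act_red))
    s.t += dt


def _check_finite(s: PlantState) -> None:
    for name in ("V", "h", "h_fast", "a_blue", "a_red"):
        if not math.isfinite(getattr(s, name)):
            raise FloatingPointError(f"plant state variable {name!r} became non-finite "
                                     f"at t={s.t:.3f} ms")


def advance_tick(state: PlantState, params: PlantParams, light: LightCommand,
                 I_inj: float = 0.0, dt: float = 1.0,
                 dt_sub: float = 0.05) -> PlantState:
    """Advance the plant by one control tick (default 1 ms) with zero-order
    hold of the light command and injected current."""
    n = max(1, round(dt / dt_sub))
    s = state.copy()
    for _ in range(n):
        _substep(s, params, light.blue, light.red, I_inj, dt_sub)
    _check_finite(s)
    return s


# -- pharmacology ------------------------------------------------------------

DRUG_LABELS = ("none", "fourAP", "carbachol")


def apply_pharmacology(params: PlantParams, drug: str) -> PlantParams:
    """Return parameters with the drug-like perturbation applied.

    ``fourAP`` slows the recovery-gate closure (tau_close * f_4AP), slowing
    repolarization and prolonging the APD; ``carbachol`` accelerates it
    (tau_close * f_cch), shortening the APD.
    """
    if drug == "none":
        return params
    if drug == "fourAP":
        return replace(params, tau_close=params.tau_close * params.f_4AP)
    if drug == "carbachol":
        return replace(params, tau_close=params.tau_close * params.f_cch)
    raise ValueError(f"unknown drug label {drug!r}; expected one of {DRUG_LABELS}")
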