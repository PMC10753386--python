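"""Model-AP waveforms: setpoint container, triangular models, CSV I/O and
steady-state drug-model recording.

A *setpoint AP* is one pacing cycle of reference membrane-potential values
sampled at the 1-ms control tick.  It is the object every controller tracks,
whether it was logged from the cell itself, loaded from a file, or generated.

The four triangular models (t13, t09, t05, t01) consist of a linear upstroke
from -68 mV at 20 mV/ms to a 12-mV peak, followed by a linear decay at 1.3,
0.9, 0.5 or 0.1 mV/ms back to -68 mV, clamped at rest for the remainder of
the 1-s cycle.  The upstroke foot is placed 10 ms after cycle start, at the
end of the optical pacing pulse.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .plant import (DARK, LightCommand, PlantParams, advance_tick,
                    apply_pharmacology, resting_state)

__all__ = [
    "SetpointAP",
    "TriangularSpec",
    "TRIANGULAR_RATES",
    "triangular_model",
    "named_triangular",
    "load_model_ap",
    "save_model_ap",
    "record_drug_model",
]

CONTROL_DT = 1.0  # ms; the fixed control-loop step


@dataclass(frozen=True)
class SetpointAP:
    """One cycle of reference V_m values, one sample per control tick."""

    values: np.ndarray
    origin: str = "generator"          # logged | file | generator
    dt: float = CONTROL_DT

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("setpoint needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("setpoint contains non-finite values")
        if self.dt != CONTROL_DT:
            raise ValueError("setpoint must be sampled at the 1-ms control step")
        if self.origin not in ("logged", "file", "generator"):
            raise ValueError(f"unknown setpoint origin {self.origin!r}")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, i: int) -> float:
        return float(self.values[i])

    @property
    def V_rest(self) -> float:
        """Resting level of the model: its final (post-repolarization) sample."""
        return float(self.values[-1])


# -- triangular models -------------------------------------------------------

TRIANGULAR_RATES = {"t13": 1.3, "t09": 0.9, "t05": 0.5, "t01": 0.1}


@dataclass(frozen=True)
class TriangularSpec:
    """Two-phase (linear upstroke / linear decay) AP model."""

    repol_rate: float              # mV/ms
    V_start: float = -68.0         # mV
    upstroke_rate: float = 20.0    # mV/ms
    V_peak: float = 12.0           # mV
    cycle_ms: int = 1000
    onset_ms: int = 10             # upstroke foot, ms after cycle start

    def __post_init__(self) -> None:
        if self.V_peak <= self.V_start:
            raise ValueError("V_peak must exceed V_start")
        if self.repol_rate <= 0 or self.upstroke_rate <= 0:
            raise ValueError("rates must be positive")


def triangular_model(spec: TriangularSpec) -> SetpointAP:
    """Sample a triangular model at the 1-ms tick.

    The peak sample is placed at the analytic peak time rounded to the
    nearest tick; the decay is clamped at ``V_start`` once repolarization
    completes.
    """
    amp = spec.V_peak - spec.V_start
    t_peak = spec.onset_ms + amp / spec.upstroke_rate
    t_end = t_peak + amp / spec.repol_rate
    if t_end >= spec.cycle_ms:
        raise ValueError(
            f"repolarization ends at {t_end:.1f} ms, beyond the {spec.cycle_ms}-ms cycle")
    t = np.arange(spec.cycle_ms, dtype=float)
    k_peak = round(t_peak)
    v = np.full(spec.cycle_ms, spec.V_start)
    up = (t >= spec.onset_ms) & (t < k_peak)
    v[up] = spec.V_start + spec.upstroke_rate * (t[up] - spec.onset_ms)
    down = t >= k_peak
    v[down] = np.maximum(spec.V_peak - spec.repol_rate * (t[down] - t_peak), spec.V_start)
    v[k_peak] = spec.V_peak
    return SetpointAP(values=v, origin="generator")


def named_triangular(name: str, **overrides) -> SetpointAP:
    """Generate one of the named models t13/t09/t05/t01."""
    try:
        rate = TRIANGULAR_RATES[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {sorted(TRIANGULAR_RATES)}")
    return triangular_model(TriangularSpec(repol_rate=rate, **overrides))


# -- file I/O ----------------------------------------------------------------

_HEADER = ("t_ms", "Vm_mV")


def save_model_ap(setpoint: SetpointAP, path) -> None:
    """Write a model AP as two-column CSV ``t_ms,Vm_mV`` at 1-ms spacing."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for i, v in enumerate(setpoint.values):
            w.writerow([f"{i * setpoint.dt:.1f}", repr(float(v))])


def load_model_ap(path) -> SetpointAP:
    """Load a model AP, validating the header, 1-ms spacing and finiteness."""
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != list(_HEADER):
            raise ValueError(f"{path}: expected header 't_ms,Vm_mV', got {header}")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: malformed row {row_no}: {row!r}")
            if not (math.isfinite(t) and math.isfinite(v)):
                raise ValueError(f"{path}: non-finite value at row {row_no}")
            times.append(t)
            values.append(v)
    if len(values) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    dt = np.diff(times)
    bad = np.nonzero(np.abs(dt - CONTROL_DT) > 1e-6)[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 3}: "
            f"spacing {dt[bad[0]]:.3f} ms (need {CONTROL_DT} ms)")
    return SetpointAP(values=np.array(values), origin="file")


# -- drug models recorded from the plant -------------------------------------

def record_drug_model(params: PlantParams, drug: str = "none",
                      period_ms: int = 1000, pacing: str = "electrical",
                      stim_level: float = 15.0, stim_ms: int = 5,
                      opt_level: float = 0.5 / 1.5, opt_ms: int = 10,
                      max_beats: int = 20, tol_mV: float = 0.5) -> SetpointAP:
    """Pace the plant under a drug to periodic steady state and return one
    cycle as a model AP.

    ``pacing`` selects electrical (``stim_level`` mV/ms for ``stim_ms`` ms)
    or optical (``opt_level`` normalized blue for ``opt_ms`` ms) stimulation
    at the start of each cycle.  Models meant for optically paced waveform
    enforcement are best recorded optically so that the model's upstroke and
    peak reflect the same pacing modality.  Steady state is declared when
    two consecutive cycles agree sample-wise within ``tol_mV``; failing that
    within ``max_beats`` beats raises.
    """
    if pacing not in ("electrical", "optical"):
        raise ValueError(f"unknown pacing mode {pacing!r}")
    p = apply_pharmacology(params, drug)
    state = resting_state(p)
    prev: np.ndarray | None = None
    for _ in range(max_beats):
        cycle = np.empty(period_ms)
        for i in range(period_ms):
            cycle[i] = state.V
            if pacing == "electrical":
                I, light = (stim_level if i < stim_ms else 0.0), DARK
            else:
                I = 0.0
                light = LightCommand(opt_level, 0.0) if i < opt_ms else DARK
            state = advance_tick(state, p, light, I_inj=I)
        if prev is not None and np.max(np.abs(cycle - prev)) < tol_mV:
            return SetpointAP(values=cycle, origin="generator")
        prev = cycle
    raise RuntimeError(
        f"plant did not reach a periodic steady state within {max_beats} beats "
        f"(drug={drug!r})")
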