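"""Quantification of action-potential traces and control error.

Conventions (shared by every analysis in the package):

* AP timing is referenced to the moment of maximal upstroke velocity,
  t(dV/dt_max), taken as the earliest tick at which the discrete forward
  difference of V_m is maximal after the stimulus.
* APD_x is the interval from t(dV/dt_max) to the time at which V_m crosses
  the x% repolarization level  V_peak - x * (V_peak - V_rest); crossings are
  located by linear interpolation between bracketing 1-ms samples.
* V_rest is the mean of the 50 ms preceding the stimulus (or of whatever
  shorter pre-stimulus segment exists).
* V_m error is measured - reference, restricted to the window from
  t(dV/dt_max) to t(APD_90) of the measured beat.
* Error distributions use 5-mV bins centered on zero, so the center bin is
  [-2.5, +2.5); the fraction of samples within +/-2.5 mV equals the center
  bin mass by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "APMetrics",
    "ErrorStats",
    "ap_metrics",
    "vm_error",
    "error_stats",
    "compare_apd",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.2, 0.3, 0.5, 0.9)


@dataclass(frozen=True)
class APMetrics:
    """Per-beat AP descriptors (times in ms from the start of the trace)."""

    t_dvdt_max: float
    dvdt_max: float
    V_peak: float
    V_rest: float
    APD: Mapping[float, float]      # fraction -> duration (ms); missing if no crossing
    t_repol: Mapping[float, float]  # fraction -> absolute crossing time (ms)

    def __post_init__(self) -> None:
        fr = sorted(self.APD)
        apds = [self.APD[f] for f in fr]
        if any(b <= a for a, b in zip(apds, apds[1:])):
            raise ValueError("APD must be strictly increasing in repolarization fraction")
        if self.V_peak <= self.V_rest:
            raise ValueError("V_peak must exceed V_rest")


def ap_metrics(trace: Sequence[float], fractions: Sequence[float] = DEFAULT_FRACTIONS,
               stim_tick: int = 0, dt: float = 1.0) -> APMetrics:
    """Measure one stimulated AP sampled uniformly at ``dt`` (default 1 ms).

    ``stim_tick`` is the index of the stimulus; the upstroke is searched from
    there on.  Fractions without a crossing before the end of the trace are
    omitted from the APD/t_repol maps.
    """
    v = np.asarray(trace, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("trace must be a 1-D array with at least 3 samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("trace contains non-finite samples")

    dv = np.diff(v) / dt
    k = stim_tick + int(np.argmax(dv[stim_tick:]))   # earliest max (argmax ties -> first)
    t_up = k * dt
    dvdt_max = float(dv[k])

    pre = v[max(0, stim_tick - round(50.0 / dt)):stim_tick]
    V_rest = float(pre.mean()) if pre.size else float(v[0])
    i_peak = k + int(np.argmax(v[k:]))
    V_peak = float(v[i_peak])

    apd: dict[float, float] = {}
    t_rep: dict[float, float] = {}
    for f in fractions:
        level = V_peak - f * (V_peak - V_rest)
        t_cross = _first_downward_crossing(v, i_peak, level, dt)
        if t_cross is not None:
            t_rep[f] = t_cross
            apd[f] = t_cross - t_up
    return APMetrics(t_dvdt_max=t_up, dvdt_max=dvdt_max, V_peak=V_peak,
                     V_rest=V_rest, APD=apd, t_repol=t_rep)


def _first_downward_crossing(v: np.ndarray, start: int, level: float,
                             dt: float) -> float | None:
    """Time of the first downward crossing of ``level`` after ``start``,
    linearly interpolated between bracketing samples."""
    below = np.nonzero(v[start + 1:] <= level)[0]
    if below.size == 0:
        return None
    j = start + 1 + below[0]
    v0, v1 = v[j - 1], v[j]
    if v1 == v0:
        return j * dt
    frac = (v0 - level) / (v0 - v1)
    return (j - 1 + frac) * dt


def vm_error(trace: Sequence[float], reference: Sequence[float],
             stim_tick: int = 0, dt: float = 1.0) -> np.ndarray:
    """Per-sample V_m error (measured - reference) over the AP time course.

    The window runs from t(dV/dt_max) to t(APD_90) of the *measured* beat;
    a beat whose 90% repolarization is never reached raises, since the window
    is then undefined.
    """
    v = np.asarray(trace, dtype=float)
    r = np.asarray(reference, dtype=float)
    if v.shape != r.shape:
        raise ValueError("trace and reference must share the same tick grid")
    m = ap_metrics(v, fractions=(0.9,), stim_tick=stim_tick, dt=dt)
    if 0.9 not in m.APD:
        raise ValueError("APD_90 undefined for this beat; error window cannot be formed")
    i0 = round(m.t_dvdt_max / dt)
    i1 = round(m.t_repol[0.9] / dt)
    return v[i0:i1 + 1] - r[i0:i1 + 1]


@dataclass(frozen=True)
class ErrorStats:
    """Distributional summary of V_m error samples (5-mV bins around zero)."""

    median: float
    frac_within_2p5: float
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    max_error: float
    t_max_error: float
    n: int


def error_stats(errors: Sequence[float], dt: float = 1.0,
                bin_width: float = 5.0) -> ErrorStats:
    """Histogram/median summary of error samples.

    Bins are ``bin_width`` wide and centered on zero (center bin
    [-w/2, +w/2)), extended symmetrically to cover every sample.
    """
    e = np.asarray(errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("no error samples")
    half = bin_width / 2.0
    k = int(np.ceil((np.abs(e).max() + half) / bin_width - 0.5)) + 1
    edges = (np.arange(-k, k + 1) - 0.5) * bin_width + 0.0
    # np.histogram's last bin is closed; widen it marginally so every bin is
    # effectively half-open [lo, hi) as stated.
    counts, _ = np.histogram(e, bins=np.append(edges[:-1], edges[-1] + 1e-9))
    center = np.count_nonzero((e >= -half) & (e < half))
    i_max = int(np.argmax(np.abs(e)))
    return ErrorStats(
        median=float(np.median(e)),
        frac_within_2p5=center / e.size,
        bin_edges=edges,
        counts=counts,
        max_error=float(e[i_max]),
        t_max_error=i_max * dt,
        n=e.size,
    )


def compare_apd(group_a: Sequence[Mapping[float, float]],
                group_b: Sequence[Mapping[float, float]]) -> dict[float, tuple[float, float]]:
    """Mean and SD of per-beat APD differences (a - b), per fraction.

    Both groups are sequences of APD maps (fraction -> ms) of equal length;
    beats are paired by position.
    """
    if not group_a or len(group_a) != len(group_b):
        raise ValueError("groups must be non-empty and of equal length")
    fracs = set(group_a[0])
    for m in list(group_a) + list(group_b):
        if set(m) != fracs:
            raise ValueError("all beats must report the same repolarization fractions")
    out: dict[float, tuple[float, float]] = {}
    for f in sorted(fracs):
        d = np.array([a[f] - b[f] for a, b in zip(group_a, group_b)])
        out[f] = (float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0)
    return out
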