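"""Shared fixtures: plant parameters, paced beats and scenario runs.

Closed-loop runs are expensive (tens of simulated beats each), so every
scenario needed by more than one test is run once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from optoclamp import (ApqrGains, ControllerSpec, DARK, Disturbance,
                       LightCommand, Pacing, PidGains, Protocol,
                       advance_tick, default_params, named_triangular,
                       record_drug_model, resting_state, run_enforcement,
                       run_restoration)

OPTICAL = Pacing(mode="optical", pulse_ms=10, pulse_level=0.5 / 1.5)


@pytest.fixture(scope="session")
def plant():
    return default_params()


@pytest.fixture(scope="session")
def paced_beats(plant):
    """Six electrically paced CTL beats (1 Hz, 5-ms 15-mV/ms pulse)."""
    state = resting_state(plant)
    beats = []
    for _ in range(6):
        cyc = np.empty(1000)
        for i in range(1000):
            cyc[i] = state.V
            state = advance_tick(state, plant, DARK,
                                 I_inj=15.0 if i < 5 else 0.0)
        beats.append(cyc)
    return beats


def paced_apd90(params, n_beats=8, fractions=(0.9,)):
    from optoclamp import ap_metrics
    state = resting_state(params)
    for _ in range(n_beats):
        cyc = np.empty(1000)
        for i in range(1000):
            cyc[i] = state.V
            state = advance_tick(state, params, DARK,
                                 I_inj=15.0 if i < 5 else 0.0)
    return ap_metrics(cyc, fractions=fractions).APD[0.9]


def _restoration(plant, algorithm, actuation, scale, *, drug="none",
                 disturbance=None, pacing=None, control=True):
    gains = (ApqrGains(scale=scale) if algorithm == "apqr"
             else PidGains(scale=scale))
    spec = ControllerSpec(algorithm=algorithm, gains=gains, actuation=actuation)
    kwargs = dict(drug=drug, correcting_beats=10, control=control)
    if drug != "none":
        kwargs["paused_beats"] = 10
    if disturbance is not None:
        kwargs["disturbance"] = disturbance
    if pacing is not None:
        kwargs["pacing"] = pacing
    return run_restoration(plant, spec, Protocol(**kwargs))


@pytest.fixture(scope="session")
def restoration_logs(plant):
    """Control-ON logs of the four restoration scenarios."""
    return {
        "current_4ap": _restoration(plant, "apqr", "current", 1.0,
                                    drug="fourAP"),
        "red_4ap": _restoration(plant, "apqr", "single_optical", 0.05,
                                drug="fourAP"),
        "dual_disturb": _restoration(plant, "apqr_pid", "dual_optical",
                                     PidGains().scale,
                                     disturbance=Disturbance(),
                                     pacing=OPTICAL),
        "dual_4ap": _restoration(plant, "apqr_pid", "dual_optical",
                                 PidGains().scale, drug="fourAP"),
    }


@pytest.fixture(scope="session")
def restoration_logs_off(plant):
    """Control-OFF counterparts (perturbation applied, output disabled)."""
    return {
        "current_4ap": _restoration(plant, "apqr", "current", 1.0,
                                    drug="fourAP", control=False),
        "red_4ap": _restoration(plant, "apqr", "single_optical", 0.05,
                                drug="fourAP", control=False),
        "dual_disturb": _restoration(plant, "apqr_pid", "dual_optical",
                                     PidGains().scale,
                                     disturbance=Disturbance(),
                                     pacing=OPTICAL, control=False),
        "dual_4ap": _restoration(plant, "apqr_pid", "dual_optical",
                                 PidGains().scale, drug="fourAP",
                                 control=False),
    }


@pytest.fixture(scope="session")
def enforcement_logs(plant):
    """APqrLE runs: the carbachol drug model and the four triangular models."""
    gains = PidGains()
    logs = {}
    cch = record_drug_model(plant, "carbachol", pacing="optical")
    logs["carbachol"] = run_enforcement(plant, gains, cch, n_beats=8,
                                        ctl_beats=2)
    for name in ("t13", "t09", "t05", "t01"):
        logs[name] = run_enforcement(plant, gains, named_triangular(name),
                                     n_beats=8, ctl_beats=2)
    return logs
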