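"""End-to-end jet-lag re-entrainment experiments.

A scenario selects a transport system (its PK parameters and published
controller tuning), a sequence of reference phase shifts (the canonical
experiment: a 5-h advance at t = 0 followed three days later by an 11-h
delay), a plant mismatch setting, and a duration (default 10 days).  The
closed loop is run and, per shift event, the time to a complete phase reset
is extracted.

A reset is counted at the first entry into the dead zone after which the
phase error stays inside for 24 consecutive hours, truncated at the next
shift event (or the scenario end) if that comes sooner; ``None`` marks a
reset never achieved.

The drug-to-clock coupling gain is "ceiling-normalized" per substrate: a
single dose at the published cumulative bound u_max drives the peak brain
concentration exactly to the coupling ceiling, mirroring the published
rationale that u_max was chosen so the maximal brain level hits the same
saturating clock effect for every substrate.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .circadian import OMEGA, DrugCoupling, IpPRC, ReferencePhase, SurrogatePlant
from .metrics import peak_stats
from .mpc import MPCConfig, closed_loop
from .pk import DoseEvent, PKParams, builtin_params, simulate_pk

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "builtin_tuning",
    "ceiling_normalized_gain",
    "run_jetlag_scenario",
    "reset_times",
]

#: dwell (min) the error must stay inside the dead zone to certify a reset
RESET_DWELL = 24.0 * 60.0


def builtin_tuning(label: str) -> dict:
    """Published (u_max, w_u) controller tuning for a transport system."""
    text = resources.files("chronodose.data").joinpath("mpc_tuning.yaml").read_text()
    table = yaml.safe_load(text)
    try:
        return dict(table[label])
    except KeyError:
        raise KeyError(f"no controller tuning for transport system {label!r}") from None


def ceiling_normalized_gain(
    params: PKParams, u_max: float, cap: float = 3.0 * OMEGA, horizon: float = 1440.0
) -> float:
    """Coupling gain placing the single-u_max-dose brain peak at the ceiling."""
    traj = simulate_pk(params, [DoseEvent(0.0, u_max)], horizon=horizon, step=1.0)
    peak_yb, _ = peak_stats(traj.times, traj.yb)
    if peak_yb <= 0:
        raise ValueError("dose produces no brain exposure; cannot normalize the gain")
    return cap / peak_yb


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one closed-loop experiment."""

    model: str = "passive_diffusion"
    #: (time_min, shift_hours) pairs; positive = advance, negative = delay
    shift_events: tuple[tuple[float, float], ...] = (
        (0.0, 5.0),
        (72.0 * 60.0, -11.0),
    )
    duration: float = 10.0 * 24.0 * 60.0
    seed: int = 0
    #: plant mismatch knobs (1.0 = matched)
    plant_omega_factor: float = 1.0
    plant_prc_scale: float = 1.0
    #: surrogate ipPRC shape
    prc_amplitude: float = 1.0
    prc_psi: float = 0.0
    coupling_cap: float = 3.0 * OMEGA
    #: controller overrides (None = published tuning for the model)
    u_max: float | None = None
    w_u: float | None = None
    tau: float = 120.0
    Np: int = 3
    delta_phi: float = 0.1

    def __post_init__(self) -> None:
        for time_min, _hours in self.shift_events:
            if not 0 <= time_min < self.duration:
                raise ValueError(f"shift event at {time_min} min outside the scenario")


@dataclass
class ScenarioResult:
    """Closed-loop log plus per-event reset metrics."""

    spec: ScenarioSpec
    log: pd.DataFrame
    reset_hours: tuple[float | None, ...]  # per shift event; None = not achieved
    total_dose: float

    def summary(self) -> str:
        parts = []
        for (t_ev, hours), reset in zip(self.spec.shift_events, self.reset_hours):
            kind = "advance" if hours > 0 else "delay"
            label = "N/A" if reset is None else f"{reset:.1f} h"
            parts.append(f"{abs(hours):g}-h {kind} at {t_ev / 60:g} h: reset in {label}")
        parts.append(f"total dosed mass {self.total_dose:.2f} mg")
        return "; ".join(parts)


def reset_times(
    log: pd.DataFrame,
    shift_events,
    duration: float,
    delta_phi: float = 0.1,
    dwell: float = RESET_DWELL,
) -> tuple[float | None, ...]:
    """Per-event time (h) from the shift to a certified phase reset.

    Certification requires the logged phase distance to stay below
    ``delta_phi`` from the entry point for ``dwell`` minutes, truncated at
    the next shift event or the end of the log.
    """
    times = log["time_min"].to_numpy()
    h = log["h_phi"].to_numpy()
    boundaries = sorted(t for t, _ in shift_events) + [duration]
    out: list[float | None] = []
    for t_ev, _hours in shift_events:
        t_end = min(b for b in boundaries if b > t_ev)
        # the log row at t_end is already measured against the next event's
        # reference, so the window is open on the right
        mask = (times > t_ev) & (times < t_end)
        tt, hh = times[mask], h[mask]
        found: float | None = None
        for i in range(len(tt)):
            if hh[i] >= delta_phi:
                continue
            need = min(dwell, t_end - tt[i])
            inside = hh[(tt > tt[i]) & (tt <= tt[i] + need)] < delta_phi
            if inside.all():
                found = (tt[i] - t_ev) / 60.0
                break
        out.append(found)
    return tuple(out)


def run_jetlag_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Build the plant and controller for ``spec`` and run the closed loop."""
    params = builtin_params(spec.model)
    tuning = builtin_tuning(spec.model)
    u_max = spec.u_max if spec.u_max is not None else float(tuning["umax"])
    w_u = spec.w_u if spec.w_u is not None else float(tuning["wu"])
    prc = IpPRC.harmonic(amplitude=spec.prc_amplitude, psi=spec.prc_psi)
    coupling = DrugCoupling(
        gain=ceiling_normalized_gain(params, u_max, cap=spec.coupling_cap),
        cap=spec.coupling_cap,
    )
    config = MPCConfig(
        tau=spec.tau,
        Np=spec.Np,
        w_u=w_u,
        u_max=u_max,
        delta_phi=spec.delta_phi,
        multistart_seed=spec.seed,
    )
    reference = ReferencePhase(
        shift_events=tuple((t, hours) for t, hours in spec.shift_events)
    )
    plant = SurrogatePlant(
        params,
        prc,
        coupling,
        omega_factor=spec.plant_omega_factor,
        prc_scale=spec.plant_prc_scale,
    )
    log = closed_loop(plant, params, prc, config, coupling, reference, spec.duration)
    resets = reset_times(log, spec.shift_events, spec.duration, spec.delta_phi)
    return ScenarioResult(
        spec=spec,
        log=log,
        reset_hours=resets,
        total_dose=float(log["u_mg"].sum()),
    )
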