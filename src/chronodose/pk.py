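"""Three-compartment oral pharmacokinetic models of blood-brain barrier transport.

All models share the gut -> plasma -> brain compartment chain under impulsive
oral dosing.  Three transport families describe the plasma -> brain step:

* ``passive_diffusion`` -- first-order, concentration-gradient-driven transfer
  (the melatonin-like case),
* ``carrier_mediated`` -- saturable Michaelis-Menten transport through a
  BBB carrier protein (amine, neutral amino acid and T3 systems),
* ``nanoparticle`` -- first-order reversible exchange (adsorptive transcytosis
  of polymeric nanoparticles).

States are drug masses (mg); outputs are concentrations (mg/mL) obtained by
dividing plasma and brain masses by the respective distribution volumes.
Time is in minutes everywhere; values supplied in hours must be converted at
the call boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PKParams",
    "DoseEvent",
    "PKTrajectory",
    "pk_derivatives",
    "simulate_pk",
    "mass_balance",
    "builtin_params",
    "builtin_labels",
    "load_params",
]

FAMILIES = ("passive_diffusion", "carrier_mediated", "nanoparticle")

#: fields each family must carry (beyond F, ka, ke, Vp, Vb shared by all)
_REQUIRED = {
    "passive_diffusion": ("kbb", "kebb"),
    "carrier_mediated": ("Vmax", "km", "kebb"),
    "nanoparticle": ("kbb", "kebb"),
}
_FORBIDDEN = {
    "passive_diffusion": ("Vmax", "km"),
    "carrier_mediated": ("kbb",),
    "nanoparticle": ("Vmax", "km"),
}


class ConfigurationError(ValueError):
    """A parameter set is incomplete or inconsistent for its model family."""


@dataclass(frozen=True)
class PKParams:
    """Parameter set for one transport model.

    Rates are in 1/min, volumes in mL, ``Vmax`` in mg/min.  ``km`` is by
    default the plasma *concentration* (mg/mL) at which carrier transport
    runs at half its maximal rate; set ``km_is_concentration=False`` to read
    it as a plasma mass (mg) instead.  ``F`` is the oral bioavailability
    fraction in (0, 1].
    """

    model_family: str
    F: float
    ka: float
    ke: float
    Vp: float
    Vb: float
    kbb: float | None = None
    kebb: float | None = None
    Vmax: float | None = None
    km: float | None = None
    label: str = ""
    #: half-saturation read as concentration (mg/mL) vs mass (mg)
    km_is_concentration: bool = True
    #: nanoparticle family: include first-order plasma elimination -ke*x2
    plasma_elimination: bool = True

    def __post_init__(self) -> None:
        if self.model_family not in FAMILIES:
            raise ConfigurationError(
                f"unknown model family {self.model_family!r}; expected one of {FAMILIES}"
            )
        if not (0.0 < self.F <= 1.0):
            raise ConfigurationError(f"bioavailability F={self.F} outside (0, 1]")
        for name in ("ka", "ke", "Vp", "Vb"):
            value = getattr(self, name)
            if value is None or value <= 0.0:
                raise ConfigurationError(f"parameter {name!r} must be strictly positive")
        for name in _REQUIRED[self.model_family]:
            value = getattr(self, name)
            if value is None or value <= 0.0:
                raise ConfigurationError(
                    f"model family {self.model_family!r} requires strictly positive {name!r}"
                )
        for name in _FORBIDDEN[self.model_family]:
            if getattr(self, name) is not None:
                raise ConfigurationError(
                    f"parameter {name!r} does not apply to family {self.model_family!r}"
                )

    @property
    def km_mass(self) -> float:
        """Half-saturation expressed as a plasma mass (mg)."""
        if self.km is None:
            raise ConfigurationError("km undefined for this model family")
        return self.km * self.Vp if self.km_is_concentration else self.km

    def with_(self, **changes) -> "PKParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class DoseEvent:
    """An oral dose: ``amount`` mg swallowed at ``time`` minutes.

    The dose enters the gut compartment as an impulse of effective mass
    ``F * amount`` (bioavailability folded into the input, so the plasma-side
    models never see the unabsorbed fraction).
    """

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time {self.time} < 0")
        if self.amount < 0:
            raise ValueError(f"dose amount {self.amount} < 0")


@dataclass
class PKTrajectory:
    """Time-gridded compartment masses and output concentrations."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3): x1 gut, x2 plasma, x3 brain (mg)
    params: PKParams
    doses: tuple[DoseEvent, ...]

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def x3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def yp(self) -> np.ndarray:
        """Plasma concentration (mg/mL)."""
        return self.states[:, 1] / self.params.Vp

    @property
    def yb(self) -> np.ndarray:
        """Brain concentration (mg/mL)."""
        return self.states[:, 2] / self.params.Vb

    @property
    def total_dose(self) -> float:
        return float(sum(d.amount for d in self.doses))

    @property
    def effective_dose(self) -> float:
        """Bioavailable mass actually delivered to the gut (mg)."""
        return self.params.F * self.total_dose

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "x1_mg": self.x1,
                "x2_mg": self.x2,
                "x3_mg": self.x3,
                "yp_mg_per_ml": self.yp,
                "yb_mg_per_ml": self.yb,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# right-hand sides


def pk_derivatives(
    state: Sequence[float], params: PKParams, input_rate: float = 0.0
) -> tuple[float, float, float]:
    """Time derivative of the compartment masses at ``state`` (mg/min).

    ``input_rate`` is an already-bioavailable gut inflow in mg/min; impulsive
    dosing is handled by the simulator, not here.
    """
    x1, x2, x3 = state
    dx1 = -params.ka * x1 + input_rate
    if params.model_family == "passive_diffusion":
        dx2 = params.ka * x1 - params.ke * x2 - params.kbb * x2
        dx3 = params.kbb * x2 - params.kebb * x3
    elif params.model_family == "carrier_mediated":
        influx = carrier_influx(x2, params)
        dx2 = params.ka * x1 - influx - params.ke * x2
        dx3 = influx - params.kebb * x3
    else:  # nanoparticle
        ke = params.ke if params.plasma_elimination else 0.0
        dx2 = params.ka * x1 - params.kbb * x2 + params.kebb * x3 - ke * x2
        dx3 = params.kbb * x2 - params.kebb * x3
    return dx1, dx2, dx3


def carrier_influx(x2: float, params: PKParams) -> float:
    """Michaelis-Menten plasma->brain transport rate (mg/min).

    Saturates at ``Vmax`` as the plasma amount far exceeds the half-saturation
    point; reduces to ``(Vmax / km_mass) * x2`` in the linear regime.
    """
    km = params.km_mass
    return params.Vmax * x2 / (km + x2)


# ---------------------------------------------------------------------------
# integration


def _group_doses(doses: Iterable[DoseEvent], step: float, horizon: float) -> dict[int, float]:
    """Map internal step index -> summed dose amount (simultaneous doses add)."""
    grouped: dict[int, float] = {}
    for dose in doses:
        if not 0.0 <= dose.time <= horizon:
            raise ValueError(f"dose at t={dose.time} outside [0, {horizon}] min")
        idx = int(round(dose.time / step))
        if abs(idx * step - dose.time) > 1e-9 * max(1.0, dose.time):
            raise ValueError(
                f"dose time {dose.time} min does not align with the {step}-min internal step"
            )
        grouped[idx] = grouped.get(idx, 0.0) + dose.amount
    return grouped


def _rk4_step(f: Callable, x: tuple[float, float, float], dt: float):
    a = f(x)
    xb = (x[0] + 0.5 * dt * a[0], x[1] + 0.5 * dt * a[1], x[2] + 0.5 * dt * a[2])
    b = f(xb)
    xc = (x[0] + 0.5 * dt * b[0], x[1] + 0.5 * dt * b[1], x[2] + 0.5 * dt * b[2])
    c = f(xc)
    xd = (x[0] + dt * c[0], x[1] + dt * c[1], x[2] + dt * c[2])
    d = f(xd)
    return (
        x[0] + dt / 6.0 * (a[0] + 2 * b[0] + 2 * c[0] + d[0]),
        x[1] + dt / 6.0 * (a[1] + 2 * b[1] + 2 * c[1] + d[1]),
        x[2] + dt / 6.0 * (a[2] + 2 * b[2] + 2 * c[2] + d[2]),
    )


def simulate_pk(
    params: PKParams,
    doses: Sequence[DoseEvent],
    horizon: float,
    step: float = 5.0,
    internal_step: float = 0.5,
    x0: Sequence[float] = (0.0, 0.0, 0.0),
    method: str = "rk4",
) -> PKTrajectory:
    """Integrate the compartment ODEs on a fixed output grid.

    ``horizon`` and ``step`` are minutes; outputs are sampled every ``step``
    minutes while the integrator advances at ``internal_step`` (default a
    classical fourth-order Runge-Kutta scheme at 0.5 min; ``method="euler"``
    selects the forward-Euler variant the state estimator is built on, in
    which case ``internal_step`` should equal ``step``).

    Each :class:`DoseEvent` is applied as an instantaneous gut-mass increment
    of ``F * amount`` at its (step-aligned) time, before the interval that
    starts there is integrated.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if step <= 0 or internal_step <= 0:
        raise ValueError("step sizes must be positive")
    if step > horizon:
        raise ValueError(f"output step {step} exceeds horizon {horizon}")
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown integration method {method!r}")
    n_sub = int(round(step / internal_step))
    if abs(n_sub * internal_step - step) > 1e-9:
        raise ValueError("output step must be an integer multiple of internal step")
    n_out = int(round(horizon / step))
    if abs(n_out * step - horizon) > 1e-9:
        raise ValueError("horizon must be an integer multiple of the output step")

    dose_at = _group_doses(doses, internal_step, horizon)
    f = lambda x: pk_derivatives(x, params)  # noqa: E731 - hot path
    x = (float(x0[0]), float(x0[1]), float(x0[2]))
    if min(x) < 0:
        raise ValueError("initial state must be nonnegative")
    dt = internal_step
    out = np.empty((n_out + 1, 3))
    if 0 in dose_at:
        x = (x[0] + params.F * dose_at[0], x[1], x[2])
    out[0] = x
    for k in range(n_out):
        for j in range(n_sub):
            idx = k * n_sub + j
            if idx != 0 and idx in dose_at:
                x = (x[0] + params.F * dose_at[idx], x[1], x[2])
            if method == "rk4":
                x = _rk4_step(f, x, dt)
            else:
                d = f(x)
                x = (x[0] + dt * d[0], x[1] + dt * d[1], x[2] + dt * d[2])
        out[k + 1] = x
    final_idx = n_out * n_sub
    if final_idx in dose_at:  # a dose exactly at the horizon end
        x = (x[0] + params.F * dose_at[final_idx], x[1], x[2])
        out[n_out] = x
    times = np.arange(n_out + 1) * step
    return PKTrajectory(times=times, states=out, params=params, doses=tuple(doses))


def mass_balance(traj: PKTrajectory) -> np.ndarray:
    """Mass-conservation residual of a dose-free stretch of trajectory.

    Compares the total drug mass at each grid time against the initial total
    minus the eliminated mass (Simpson quadrature of the plasma and brain
    elimination flows).  Dosing impulses between grid points are credited analytically.
    Near-zero residuals certify that the integrator respects the book-keeping
    the compartment chain implies.
    """
    p = traj.params
    x2, x3 = traj.x2, traj.x3
    total = traj.x1 + x2 + x3
    if p.model_family == "nanoparticle":
        # the brain exchange is reversible; only the plasma pathway eliminates
        ke = p.ke if p.plasma_elimination else 0.0
        elim = ke * x2
    else:
        elim = p.ke * x2 + p.kebb * x3
    from scipy.integrate import cumulative_simpson

    eliminated = cumulative_simpson(elim, x=traj.times, initial=0.0)
    dosed = np.array(
        [sum(p.F * d.amount for d in traj.doses if d.time <= t) for t in traj.times]
    )
    # total[0] already includes any dose applied at t=0
    return total - total[0] - (dosed - dosed[0]) + eliminated


# ---------------------------------------------------------------------------
# packaged parameter sets (one block per published transport-system row)


def _data_text(name: str) -> str:
    return resources.files("chronodose.data").joinpath(name).read_text()


def _params_from_block(label: str, block: dict) -> PKParams:
    fields = {k: block.get(k) for k in ("F", "ka", "ke", "kbb", "kebb", "Vp", "Vb", "Vmax", "km")}
    return PKParams(model_family=block["model_family"], label=label, **fields)


def load_params(source) -> dict[str, PKParams]:
    """Read a YAML mapping of label -> parameter block into PKParams."""
    raw = yaml.safe_load(source if isinstance(source, str) else source.read())
    return {label: _params_from_block(label, block) for label, block in raw.items()}


def builtin_params(label: str) -> PKParams:
    """Packaged parameter set for one of the five published transport systems."""
    table = load_params(_data_text("pk_parameters.yaml"))
    try:
        return table[label]
    except KeyError:
        raise KeyError(
            f"unknown transport system {label!r}; available: {sorted(table)}"
        ) from None


def builtin_labels() -> list[str]:
    return list(load_params(_data_text("pk_parameters.yaml")))
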