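"""Phase-reduced circadian oscillator driven through a parametric PRC.

The full molecular clock is collapsed to a single phase variable evolving as

    dphi/dt = omega + B(phi) * v(t),        omega = 2*pi / 24 h,

where B is the infinitesimal parametric phase response curve (ipPRC): the
sensitivity of clock phase to a small, brief perturbation of the targeted
clock parameter, as a function of the phase at which the perturbation lands.
The clock input v is derived from the brain drug concentration yb through a
saturating linear map (see :class:`DrugCoupling`); light and all other
zeitgebers are held at zero.

The package does not re-derive an ipPRC from a molecular model: B is a
configuration input (tabulated knots with periodic interpolation), with a
single-harmonic surrogate ``B(phi) = A * sin(phi + psi)`` packaged as the
default.  Positive ``B * v`` advances the phase.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "OMEGA",
    "IpPRC",
    "DrugCoupling",
    "PhaseState",
    "ReferencePhase",
    "advance_phase",
    "SurrogatePlant",
    "wrap_phase",
]

TWO_PI = 2.0 * math.pi
#: free-running angular frequency, rad/min, for the canonical 24-h period
OMEGA = TWO_PI / (24.0 * 60.0)


def wrap_phase(phi: float) -> float:
    """Reduce a phase to [0, 2*pi)."""
    return phi % TWO_PI


class IpPRC:
    """Periodic drug-sensitivity curve B(phi) on tabulated knots.

    ``knots`` are phases in [0, 2*pi) and ``values`` the sensitivity at each
    knot; evaluation between knots uses a periodic cubic spline so B(0) and
    B(2*pi) agree with matching derivatives.
    """

    def __init__(self, knots: Sequence[float], values: Sequence[float]):
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)
        if knots.ndim != 1 or knots.size < 3:
            raise ValueError("ipPRC needs at least three knots")
        if np.any(np.diff(knots) <= 0) or knots[0] < 0 or knots[-1] >= TWO_PI:
            raise ValueError("knots must be strictly increasing within [0, 2*pi)")
        if not np.all(np.isfinite(values)):
            raise ValueError("ipPRC values must be finite")
        self.knots = knots
        self.values = values
        x = np.append(knots, knots[0] + TWO_PI)
        y = np.append(values, values[0])
        self._spline = CubicSpline(x, y, bc_type="periodic")

    def __call__(self, phi):
        return self._spline(np.asarray(phi) % TWO_PI)

    def scaled(self, factor: float) -> "IpPRC":
        return IpPRC(self.knots, factor * self.values)

    @classmethod
    def harmonic(cls, amplitude: float = 1.0, psi: float = 0.0, n_knots: int = 64) -> "IpPRC":
        """Single-harmonic surrogate ``A * sin(phi + psi)``."""
        knots = np.linspace(0.0, TWO_PI, n_knots, endpoint=False)
        return cls(knots, amplitude * np.sin(knots + psi))

    @classmethod
    def from_csv(cls, source) -> "IpPRC":
        """Read tabulated knots from CSV columns (phase_rad, B_value)."""
        frame = pd.read_csv(source if not isinstance(source, str) else io.StringIO(source))
        return cls(frame["phase_rad"].to_numpy(), frame["B_value"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"phase_rad": self.knots, "B_value": self.values}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class DrugCoupling:
    """Map from brain concentration yb (mg/mL) to the clock input v (rad/min).

    ``v = min(gain * yb, cap)``: linear in concentration up to a hard ceiling
    that stands in for the saturation of the targeted clock process (the
    cryptochrome degradation rate cannot be suppressed beyond a fixed
    fraction, however much drug arrives).  The default ceiling ``3 * omega``
    lets a saturating dose at most triple -- or, on the opposite PRC lobe,
    invert -- the clock speed.
    """

    gain: float
    cap: float = 3.0 * OMEGA

    def __call__(self, yb: float) -> float:
        return min(self.gain * yb, self.cap)


@dataclass
class PhaseState:
    """Oscillator phase at a clock time."""

    phi: float
    t: float = 0.0
    omega: float = OMEGA

    def __post_init__(self) -> None:
        self.phi = wrap_phase(self.phi)


@dataclass(frozen=True)
class ReferencePhase:
    """The entrainment target: phi_r(t) = omega*t + offset, with jet-lag jumps.

    ``shift_events`` is a sequence of ``(time_min, shift_hours)`` pairs: a
    positive shift is a phase advance (local time jumps ahead, the offset
    increases by ``omega * hours * 60``), a negative one a delay.
    """

    omega: float = OMEGA
    offset: float = 0.0
    shift_events: tuple[tuple[float, float], ...] = ()

    def __call__(self, t: float) -> float:
        offset = self.offset
        for time_min, hours in self.shift_events:
            if t >= time_min:
                offset += self.omega * hours * 60.0
        return self.omega * t + offset


def advance_phase(
    state: PhaseState,
    prc: IpPRC,
    yb_series,
    dt: float,
    duration: float,
    coupling: DrugCoupling | None = None,
) -> PhaseState:
    """Integrate dphi/dt = omega + B(phi) * v over ``duration`` minutes.

    ``yb_series`` maps absolute time (min) to brain concentration; ``coupling``
    converts concentration to the clock input (identity when omitted, i.e.
    the series is already the clock input v).  Classical RK4 at step ``dt``.
    """
    if dt <= 0 or duration < 0:
        raise ValueError("dt must be positive and duration nonnegative")
    couple = coupling if coupling is not None else (lambda v: v)
    phi, t = state.phi, state.t
    omega = state.omega
    n = int(round(duration / dt))

    def rate(phi_, t_):
        return omega + float(prc(phi_)) * couple(float(yb_series(t_)))

    for _ in range(n):
        a = rate(phi, t)
        b = rate(phi + 0.5 * dt * a, t + 0.5 * dt)
        c = rate(phi + 0.5 * dt * b, t + 0.5 * dt)
        d = rate(phi + dt * c, t + dt)
        phi += dt / 6.0 * (a + 2 * b + 2 * c + d)
        t += dt
    return PhaseState(phi=wrap_phase(phi), t=t, omega=omega)


class SurrogatePlant:
    """Closed-loop plant whose dynamics are exactly the phase-reduced model.

    Stands in for the (unavailable) full molecular oscillator: stepping the
    plant co-simulates the PK compartments and the phase equation with the
    same integrator the controller's predictor uses, so that with zero
    mismatch the predictor is exact.  ``omega_factor`` and ``prc_scale``
    perturb the plant relative to the controller's model to emulate
    model/plant mismatch.
    """

    def __init__(
        self,
        params,
        prc: IpPRC,
        coupling: DrugCoupling,
        omega: float = OMEGA,
        omega_factor: float = 1.0,
        prc_scale: float = 1.0,
        phi0: float = 0.0,
        internal_step: float = 1.0,
    ):
        self.params = params
        self.prc = prc if prc_scale == 1.0 else prc.scaled(prc_scale)
        self.coupling = coupling
        self.omega = omega * omega_factor
        self.internal_step = internal_step
        self.phi = wrap_phase(phi0)
        self.t = 0.0
        self.pk_state = (0.0, 0.0, 0.0)

    def step(self, dose: float, duration: float) -> float:
        """Administer ``dose`` mg now, advance ``duration`` min, return phase."""
        from .cosim import cosimulate  # local import to avoid a cycle

        (self.pk_state, self.phi) = cosimulate(
            self.params,
            self.pk_state,
            self.phi,
            [(0.0, dose)],
            duration,
            self.internal_step,
            self.prc,
            self.coupling,
            self.omega,
        )
        self.t += duration
        return self.phi
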