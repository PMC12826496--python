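"""Analytic diffusivity relations for exosome transport.

Exosomes are nanoscale (30-150 nm) lipid vesicles; in an aqueous medium their
passive diffusivity follows the Stokes-Einstein relation

    D = k_B T / (6 pi eta r),

with r the hydrodynamic radius.  The simulator works in micrometres and
minutes, so everything here is converted to um^2/min.  A second relation
predicts the exosome diffusivity D* that maximizes the follower velocity for
a given capture radius a, leader speed v0 and initial separation l0: the
diffusive spreading sqrt(4 D t) must match the leader's retreat l0 + v0 t at
the time t ~ a / v0 over which the follower's neighbourhood is refreshed,
giving

    D* = v0 (l0 + a)^2 / (4 a).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

#: Boltzmann constant in J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

_SPEED_UNITS = {
    "um/hr": 1.0 / 60.0,
    "um/min": 1.0,
    "μm/hr": 1.0 / 60.0,
    "μm/min": 1.0,
}


@dataclass(frozen=True)
class DiffusivityContext:
    """Physical context for the Stokes-Einstein estimate.

    Parameters
    ----------
    exosome_radius_nm : float
        Hydrodynamic radius of the exosome in nanometres.  The quoted
        exosome size range 30-150 nm is interpreted as a radius; set
        ``size_is_diameter=True`` for the diameter reading.
    temperature_K : float
        Absolute temperature; default 293 K (room temperature).
    viscosity_Pa_s : float
        Dynamic viscosity of the medium; default 1.0e-3 Pa s (water).
    """

    exosome_radius_nm: float
    temperature_K: float = 293.0
    viscosity_Pa_s: float = 1.0e-3
    boltzmann_J_per_K: float = BOLTZMANN_J_PER_K
    size_is_diameter: bool = False

    def __post_init__(self) -> None:
        for name in ("exosome_radius_nm", "temperature_K", "viscosity_Pa_s",
                     "boltzmann_J_per_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GeometryContext:
    """Geometry entering the optimal-diffusivity prediction.

    capture_radius_um is the follower's detection radius a, leader_speed is
    v0 in um/min, initial_separation_um is the starting leader-follower
    distance l0.  The prediction's derivation assumes l0 > 2a (the alternate
    root of the matching condition is negative there).
    """

    capture_radius_um: float = 10.0
    leader_speed_um_min: float = 3.4 / 60.0
    initial_separation_um: float = 10.0

    def __post_init__(self) -> None:
        if self.capture_radius_um <= 0 or self.leader_speed_um_min <= 0:
            raise ValueError("capture radius and leader speed must be positive")
        if self.initial_separation_um <= 0:
            raise ValueError("initial separation must be positive")


def stokes_einstein_D(ctx: DiffusivityContext) -> float:
    """Stokes-Einstein diffusivity in um^2/min.

    For the default context, radii of 150 nm and 30 nm give ~86 and
    ~429 um^2/min, spanning the physiological band for exosome sizes.
    """
    radius_m = ctx.exosome_radius_nm * 1e-9
    if ctx.size_is_diameter:
        radius_m *= 0.5
    d_m2_per_s = ctx.boltzmann_J_per_K * ctx.temperature_K / (
        6.0 * math.pi * ctx.viscosity_Pa_s * radius_m
    )
    # m^2/s -> um^2/min: 1e12 um^2 per m^2, 60 s per min
    return d_m2_per_s * 1e12 * 60.0


def optimal_D_prediction(ctx: GeometryContext) -> float:
    """Predicted velocity-maximizing exosome diffusivity, um^2/min.

    D* = v0 (l0 + a)^2 / (4 a).  Substituting t = a/v0 back into the
    matching condition sqrt(4 D* t) = l0 + v0 t makes it exact.
    """
    a = ctx.capture_radius_um
    l0 = ctx.initial_separation_um
    if l0 <= 2.0 * a:
        warnings.warn(
            "optimal-D prediction derived for l0 > 2a; result outside its "
            "validity branch",
            stacklevel=2,
        )
    return ctx.leader_speed_um_min * (l0 + a) ** 2 / (4.0 * a)


def convert_speed(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a speed between um/hr and um/min (exact factor 60)."""
    try:
        factor = _SPEED_UNITS[from_unit] / _SPEED_UNITS[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown speed unit; expected one of {sorted(set(_SPEED_UNITS))}"
        ) from exc
    return value * factor
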