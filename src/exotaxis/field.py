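"""Exosome field: secretion, Brownian transport, degradation, detection.

Exosomes are discrete signal packets released at the leader cell's current
position.  Each carries an integer molecular cargo n_i ~ Poisson(nbar); the
leader's molecular output rate nu is fixed, so the packet rate is nu/nbar
(frequency-payload tradeoff).  Packets diffuse with per-axis Gaussian
increments of variance 2 D dt, optionally degrade as a first-order process
with timescale T (per-step probability dt/T), optionally reflect off two
walls at y = +/-L, and are absorbed on first detection within the follower's
capture radius a.

The canonical container is :class:`ExosomeField`, a struct-of-arrays over
particles; :class:`Exosome` is the single-particle record view.  The
operations in this module are the per-substep reference path, vectorized
with numpy; the production engine runs a numerically equivalent compiled
kernel (see ``exotaxis.engine``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .memory import DetectionEvent, ResponseParams, activation

__all__ = [
    "Exosome",
    "ExosomeField",
    "FieldParams",
    "SecretionParams",
    "sample_cargo",
    "secrete",
    "diffuse_step",
    "degrade_step",
    "reflect_walls",
    "fold_into_slab",
    "detect_and_absorb",
]


@dataclass(frozen=True)
class Exosome:
    """Single-particle record: position (um), integer cargo, birth time
    (min) and alive flag."""

    id: int
    x: float
    y: float
    cargo: int
    birth_time: float
    alive: bool = True

    def __post_init__(self) -> None:
        if self.cargo < 0:
            raise ValueError("cargo must be nonnegative")


@dataclass(frozen=True)
class FieldParams:
    """Transport parameters: diffusivity D (um^2/min), degradation time T
    (min, may be inf), exosome substep dt_exo (min), optional wall
    half-width L (um) and capture radius a (um)."""

    diffusivity: float = 250.0
    degradation_time: float = math.inf
    dt_exo: float = 0.1
    wall_half_width: float | None = None
    capture_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.diffusivity < 0:
            raise ValueError("diffusivity D must be nonnegative")
        if self.degradation_time <= 0:
            raise ValueError("degradation time must be positive (or inf)")
        if self.dt_exo <= 0:
            raise ValueError("dt_exo must be positive")
        if self.capture_radius <= 0:
            raise ValueError("capture radius a must be positive")
        if (
            self.wall_half_width is not None
            and self.wall_half_width <= self.capture_radius
        ):
            raise ValueError("wall half-width L must exceed the capture radius")


@dataclass(frozen=True)
class SecretionParams:
    """Molecular output rate nu (molecules/min) and mean cargo nbar
    (molecules per exosome); the implied exosome rate is nu/nbar.  A zero
    rate models a silent leader."""

    molecular_rate: float = 350.0
    mean_cargo: float = 50.0

    def __post_init__(self) -> None:
        if self.molecular_rate < 0:
            raise ValueError("molecular rate nu must be nonnegative")
        if self.mean_cargo <= 0:
            raise ValueError("mean cargo nbar must be positive")

    @property
    def exosome_rate(self) -> float:
        """Exosomes per minute, nu / nbar."""
        return self.molecular_rate / self.mean_cargo


class ExosomeField:
    """Struct-of-arrays particle container (positions, cargo, birth times,
    alive flags); grows by amortized doubling."""

    def __init__(self, capacity: int = 1024) -> None:
        capacity = max(int(capacity), 1)
        self.x = np.empty(capacity)
        self.y = np.empty(capacity)
        self.cargo = np.empty(capacity, dtype=np.int64)
        self.birth_time = np.empty(capacity)
        self.alive = np.zeros(capacity, dtype=bool)
        self.n = 0
        self._next_id = 0

    def __len__(self) -> int:
        return self.n

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n]))

    def _grow_to(self, n: int) -> None:
        if n <= len(self.x):
            return
        cap = max(n, 2 * len(self.x))
        for name in ("x", "y", "cargo", "birth_time", "alive"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def add(
        self,
        x: np.ndarray,
        y: np.ndarray,
        cargo: np.ndarray,
        birth_time: float | np.ndarray,
    ) -> np.ndarray:
        """Append new live particles; returns their integer ids."""
        k = len(np.atleast_1d(x))
        self._grow_to(self.n + k)
        sl = slice(self.n, self.n + k)
        self.x[sl] = x
        self.y[sl] = y
        self.cargo[sl] = cargo
        self.birth_time[sl] = birth_time
        self.alive[sl] = True
        ids = np.arange(self._next_id, self._next_id + k)
        self._next_id += k
        self.n += k
        return ids

    def exosomes(self) -> list[Exosome]:
        """Materialize single-particle records (ids are array indices)."""
        return [
            Exosome(
                id=i,
                x=float(self.x[i]),
                y=float(self.y[i]),
                cargo=int(self.cargo[i]),
                birth_time=float(self.birth_time[i]),
                alive=bool(self.alive[i]),
            )
            for i in range(self.n)
        ]


def sample_cargo(
    mean_cargo: float, rng: np.random.Generator, size: int | None = None
):
    """Draw integer cargo counts from Poisson(nbar); zero is a legal draw."""
    if mean_cargo <= 0:
        raise ValueError("mean cargo nbar must be positive")
    return rng.poisson(mean_cargo, size=size)


def secrete(
    leader_position: np.ndarray,
    secretion: SecretionParams,
    dt: float,
    t: float,
    rng: np.random.Generator,
    out: ExosomeField | None = None,
) -> ExosomeField:
    """Release Poisson(nu dt / nbar) new exosomes at the leader's position.

    Each newborn sits at the leader position at time t with an independent
    Poisson(nbar) cargo.  Appends to ``out`` when given (and returns it),
    else returns a fresh field holding only the newborns.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    count = int(rng.poisson(secretion.exosome_rate * dt))
    fld = out if out is not None else ExosomeField(capacity=max(count, 1))
    if count > 0:
        lx, ly = float(leader_position[0]), float(leader_position[1])
        fld.add(
            np.full(count, lx),
            np.full(count, ly),
            sample_cargo(secretion.mean_cargo, rng, size=count),
            t,
        )
    return fld


def diffuse_step(
    field: ExosomeField, D: float, dt: float, rng: np.random.Generator
) -> None:
    """Advance live particles by Gaussian displacements, variance 2 D dt
    per axis (in place)."""
    if D < 0 or dt <= 0:
        raise ValueError("require D >= 0 and dt > 0")
    if D == 0.0 or field.n == 0:
        return
    idx = np.flatnonzero(field.alive[: field.n])
    if idx.size == 0:
        return
    sigma = math.sqrt(2.0 * D * dt)
    field.x[idx] += sigma * rng.standard_normal(idx.size)
    field.y[idx] += sigma * rng.standard_normal(idx.size)


def degrade_step(
    field: ExosomeField,
    degradation_time: float,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """Kill each live particle independently with probability dt/T.

    Infinite T is a no-op; dt >= T is rejected (probability would reach 1).
    """
    if math.isinf(degradation_time):
        return
    if dt >= degradation_time:
        raise ValueError("dt must be smaller than the degradation time")
    p = dt / degradation_time
    idx = np.flatnonzero(field.alive[: field.n])
    if idx.size == 0:
        return
    killed = rng.random(idx.size) < p
    field.alive[idx[killed]] = False


def fold_into_slab(y: np.ndarray | float, half_width: float):
    """Mirror-reflect y-coordinates into the slab |y| <= L."""
    L = half_width
    y = np.asarray(y, dtype=np.float64)
    # each fold reduces the excursion; loop terminates for finite input
    while True:
        over = y > L
        under = y < -L
        if not (np.any(over) or np.any(under)):
            break
        y = np.where(over, 2.0 * L - y, y)
        y = np.where(under, -2.0 * L - y, y)
    return y


def reflect_walls(
    field: ExosomeField,
    follower_position: np.ndarray,
    wall_half_width: float,
) -> np.ndarray:
    """Reflect exosomes (in place) and the follower off walls at y = +/-L.

    Returns the follower's folded position; x-coordinates are untouched.
    """
    if wall_half_width is None:
        raise ValueError("wall_half_width must be set to reflect")
    if field.n:
        idx = np.flatnonzero(field.alive[: field.n])
        if idx.size:
            field.y[idx] = fold_into_slab(field.y[idx], wall_half_width)
    fp = np.asarray(follower_position, dtype=np.float64).copy()
    fp[1] = float(fold_into_slab(fp[1], wall_half_width))
    return fp


def detect_and_absorb(
    field: ExosomeField,
    follower_position: np.ndarray,
    capture_radius: float,
    t: float,
    response: ResponseParams,
) -> list[DetectionEvent]:
    """Absorb every live exosome within the capture radius of the follower.

    Each absorbed exosome yields one event carrying its detection time, its
    arrival angle atan2(y_i - y_f, x_i - x_f) (quadrant-aware; defined as 0
    for an exosome exactly at the follower center) and its cargo/activation.
    Absorbed exosomes are removed from the field, so no exosome ever
    contributes two events.
    """
    if capture_radius <= 0:
        raise ValueError("capture radius must be positive")
    events: list[DetectionEvent] = []
    if field.n == 0:
        return events
    fx, fy = float(follower_position[0]), float(follower_position[1])
    idx = np.flatnonzero(field.alive[: field.n])
    if idx.size == 0:
        return events
    dx = field.x[idx] - fx
    dy = field.y[idx] - fy
    hit = dx * dx + dy * dy <= capture_radius * capture_radius
    for j in idx[hit]:
        ddx = field.x[j] - fx
        ddy = field.y[j] - fy
        angle = 0.0 if (ddx == 0.0 and ddy == 0.0) else math.atan2(ddy, ddx)
        cargo = int(field.cargo[j])
        events.append(
            DetectionEvent(
                time=t,
                angle=angle,
                cargo=cargo,
                activation=activation(cargo, response),
            )
        )
        field.alive[j] = False
    return events
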