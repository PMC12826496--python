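"""Follower-cell signal processing: activation, memory, direction choice.

Each detected exosome contributes an activation alpha_i = n_i^H/(n_i^H + K^H)
(a Hill function of its realized integer cargo n_i), weighted by an
exponential memory kernel m_i(t) = exp(-(t - t_i)/tau).  The follower keeps
three decaying sums,

    M = sum_i alpha_i m_i,   S = sum_i alpha_i m_i sin(theta_i),
    C = sum_i alpha_i m_i cos(theta_i),

from which the remembered mean direction is atan2(S, C).  At every cell step
the follower moves along that direction with probability M/(1+M) and along a
uniform random direction otherwise.  Because all events share the same
exponential kernel, lazily decaying (M, S, C) by a common factor is exactly
equivalent to keeping the full event list; ``EventListMemory`` retains the
explicit-sum form as a reference implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ResponseParams",
    "DetectionEvent",
    "MemoryAccumulators",
    "EventListMemory",
    "activation",
    "activation_array",
    "decay_to",
    "register_event",
    "readout",
    "sample_direction",
    "step_follower",
    "wrap_angle",
]


def wrap_angle(theta: float) -> float:
    """Normalize an angle to the principal range (-pi, pi]."""
    theta = math.remainder(theta, 2.0 * math.pi)
    if theta <= -math.pi:
        theta += 2.0 * math.pi
    return theta


@dataclass(frozen=True)
class ResponseParams:
    """Detection response: threshold K (molecules), Hill coefficient H,
    memory time tau (minutes)."""

    threshold: float = 25.0
    hill: float = 3.0
    memory_time: float = 5.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold K must be positive")
        if self.hill < 1:
            raise ValueError("Hill coefficient H must be >= 1")
        if self.memory_time <= 0:
            raise ValueError("memory time tau must be positive")


def activation(cargo: float, params: ResponseParams) -> float:
    """Hill activation n^H / (n^H + K^H) of a realized cargo count.

    Monotone nondecreasing in cargo, exactly 1/2 at cargo == K, and in
    [0, 1) for finite cargo; zero cargo maps to zero.
    """
    if cargo < 0:
        raise ValueError("cargo must be nonnegative")
    if cargo == 0:
        return 0.0
    # 1 / (1 + (K/n)^H) is overflow-safe for any H
    return 1.0 / (1.0 + (params.threshold / cargo) ** params.hill)


def activation_array(cargo: np.ndarray, threshold: float, hill: float) -> np.ndarray:
    """Vectorized Hill activation over an integer cargo array."""
    cargo = np.asarray(cargo, dtype=np.float64)
    out = np.zeros_like(cargo)
    nz = cargo > 0
    out[nz] = 1.0 / (1.0 + (threshold / cargo[nz]) ** hill)
    return out


@dataclass(frozen=True)
class DetectionEvent:
    """One exosome detection: time t_i (min), arrival angle theta_i
    (radians, principal range), integer cargo n_i and its activation."""

    time: float
    angle: float
    cargo: int
    activation: float

    @classmethod
    def from_detection(
        cls, time: float, angle: float, cargo: int, params: ResponseParams
    ) -> "DetectionEvent":
        return cls(
            time=time,
            angle=wrap_angle(angle),
            cargo=int(cargo),
            activation=activation(cargo, params),
        )


@dataclass(frozen=True)
class MemoryAccumulators:
    """Lazily decayed memory sums (M, S, C) at time ``last_update``.

    Invariant: M >= sqrt(S^2 + C^2) (triangle inequality over the
    nonnegative weights alpha_i m_i).
    """

    M: float = 0.0
    S: float = 0.0
    C: float = 0.0
    last_update: float = 0.0

    def check(self) -> None:
        if self.M + 1e-12 * (1.0 + self.M) < math.hypot(self.S, self.C):
            raise AssertionError("memory invariant violated: M < |(S, C)|")


def decay_to(acc: MemoryAccumulators, t: float, tau: float) -> MemoryAccumulators:
    """Decay all three accumulators by exp(-(t - last_update)/tau)."""
    if t < acc.last_update:
        raise ValueError("cannot decay memory backwards in time")
    f = math.exp(-(t - acc.last_update) / tau)
    return MemoryAccumulators(M=acc.M * f, S=acc.S * f, C=acc.C * f, last_update=t)


def register_event(
    acc: MemoryAccumulators, event: DetectionEvent, tau: float
) -> MemoryAccumulators:
    """Decay to the event time, then add the event's weighted vector."""
    if event.time < acc.last_update:
        raise ValueError("detection events must be registered in time order")
    acc = decay_to(acc, event.time, tau)
    a = event.activation
    return replace(
        acc,
        M=acc.M + a,
        S=acc.S + a * math.sin(event.angle),
        C=acc.C + a * math.cos(event.angle),
    )


def readout(
    acc: MemoryAccumulators, t: float, tau: float
) -> tuple[float, float | None]:
    """Return (M, mean angle) at time t; the angle is None when S = C = 0.

    The mean angle of a single remembered event is invariant under decay
    (the kernel cancels in the S/C ratio).
    """
    acc = decay_to(acc, t, tau)
    if acc.S == 0.0 and acc.C == 0.0:
        return acc.M, None
    return acc.M, math.atan2(acc.S, acc.C)


def sample_direction(
    M: float, mean_angle: float | None, rng: np.random.Generator
) -> float:
    """Sample the follower's step direction.

    With probability M/(1+M) the remembered mean angle is taken; otherwise
    (and always when the mean angle is undefined, including the degenerate
    case of perfectly opposed detections) a uniform direction is drawn.
    Returned angles lie in (-pi, pi].
    """
    if M < 0:
        raise ValueError("M must be nonnegative")
    if mean_angle is not None and rng.random() < M / (1.0 + M):
        return wrap_angle(mean_angle)
    return wrap_angle(rng.uniform(0.0, 2.0 * math.pi))


def step_follower(
    position: np.ndarray, theta: float, v0: float, dt_cell: float
) -> np.ndarray:
    """Advance the follower by a step of length v0 * dt_cell along theta."""
    if dt_cell <= 0:
        raise ValueError("dt_cell must be positive")
    step = v0 * dt_cell
    return np.asarray(position, dtype=np.float64) + step * np.array(
        [math.cos(theta), math.sin(theta)]
    )


@dataclass
class EventListMemory:
    """Reference memory keeping the explicit event list.

    Evaluates M, S, C by direct summation of alpha_i exp(-(t - t_i)/tau);
    used to cross-check the O(1) lazily-decayed accumulators.
    """

    tau: float
    events: list[DetectionEvent] = field(default_factory=list)

    def add(self, event: DetectionEvent) -> None:
        self.events.append(event)

    def sums(self, t: float) -> tuple[float, float, float]:
        M = S = C = 0.0
        for e in self.events:
            w = e.activation * math.exp(-(t - e.time) / self.tau)
            M += w
            S += w * math.sin(e.angle)
            C += w * math.cos(e.angle)
        return M, S, C

    def readout(self, t: float) -> tuple[float, float | None]:
        M, S, C = self.sums(t)
        if S == 0.0 and C == 0.0:
            return M, None
        return M, math.atan2(S, C)
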