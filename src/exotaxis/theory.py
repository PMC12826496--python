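"""Closed-form 1D theory of the leader-follower chase, plus a 1D oracle.

In the reduced model the leader moves right at v0 and leaves a trail of
immobile exosomes (rate nu/nbar, Poisson cargo); the follower hops +/-v0*dt
with P(right) = (1/2 + M)/(1 + M).  Approximating every detection by the
mean activation abar = nbar^H/(nbar^H + K^H) and counting encounters within
one memory time gives the self-consistency M = (v/v0) * abar * tau * nu /
nbar, whose solution is the piecewise closed form

    v / v0 = max(0, 1 - phi),    phi = beta * x * (1 + x^-H),

with x = nbar/K and beta = K/(tau * nu).  For H > 1 the velocity is
maximized at x* = (H-1)^(1/H) (so nbar* ~ K), where it reaches
1 - beta * H/(H-1) * (H-1)^(1/H).  The Monte Carlo simulator in this module
implements the reduced model directly (per-exosome Poisson cargo by
default) and serves as an independent check of those approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .memory import activation_array

__all__ = [
    "Theory1DParams",
    "MC1DResult",
    "p_right",
    "phi",
    "closed_form_velocity",
    "optimal_cargo_ratio",
    "max_velocity",
    "self_consistent_solve",
    "mc_1d_simulate",
]


@dataclass(frozen=True)
class Theory1DParams:
    """Dimensionless coordinates of the 1D theory: x = nbar/K,
    beta = K/(tau nu), Hill coefficient H."""

    x: float
    beta: float
    hill: float

    def __post_init__(self) -> None:
        if self.x <= 0 or self.beta <= 0:
            raise ValueError("x and beta must be positive")
        if self.hill < 1:
            raise ValueError("Hill coefficient must be >= 1")

    @classmethod
    def from_raw(
        cls, threshold: float, memory_time: float, molecular_rate: float,
        mean_cargo: float, hill: float,
    ) -> "Theory1DParams":
        return cls(
            x=mean_cargo / threshold,
            beta=threshold / (memory_time * molecular_rate),
            hill=hill,
        )


def p_right(M: float) -> float:
    """Probability of stepping toward the leader: (1/2 + M)/(1 + M)."""
    if M < 0:
        raise ValueError("M must be nonnegative")
    return (0.5 + M) / (1.0 + M)


def phi(x: float, beta: float, hill: float) -> float:
    """Composite drag factor phi = beta x (1 + x^-H); drift requires phi < 1."""
    if x <= 0 or beta <= 0:
        raise ValueError("x and beta must be positive")
    return beta * x * (1.0 + x ** (-hill))


def closed_form_velocity(x: float, beta: float, hill: float) -> float:
    """Mean follower velocity in units of v0: 1 - phi if phi < 1, else 0."""
    f = phi(x, beta, hill)
    return 1.0 - f if f < 1.0 else 0.0


def optimal_cargo_ratio(hill: float) -> float:
    """Velocity-maximizing cargo ratio x* = nbar*/K = (H-1)^(1/H).

    Only defined for H > 1; for H <= 1 the velocity is monotone decreasing
    in x, the optimum sits at the smallest admissible cargo, and a
    ValueError flags the boundary optimum.  x* -> 1 as H -> infinity.
    """
    if hill <= 1:
        raise ValueError(
            "no interior optimum for H <= 1: velocity decreases "
            "monotonically with cargo size"
        )
    return (hill - 1.0) ** (1.0 / hill)


def max_velocity(beta: float, hill: float) -> float:
    """Peak velocity 1 - beta H/(H-1) (H-1)^(1/H), floored at 0.

    Equals the closed form evaluated at x*; tends to 1 - beta for H >> 1.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if hill <= 1:
        raise ValueError("the peak velocity formula requires H > 1")
    v = 1.0 - beta * hill / (hill - 1.0) * (hill - 1.0) ** (1.0 / hill)
    return max(0.0, v)


def self_consistent_solve(
    x: float, beta: float, hill: float, tol: float = 1e-14, max_iter: int = 500
) -> float:
    """Solve the mean-field self-consistency numerically.

    The reduced velocity u = v/v0 satisfies u = c u / (1 + c u) with
    c = 1/phi (memory built at speed u feeds back into the step bias).
    This routine exists as an independent numerical check of the closed
    form: it root-finds (for phi < 1) or fixed-point iterates (phi >= 1)
    without using the 1 - phi expression.
    """
    f = phi(x, beta, hill)
    c = 1.0 / f

    def g(u: float) -> float:
        return c * u / (1.0 + c * u)

    if f < 1.0:
        # the nonzero fixed point is bracketed away from the trivial root
        lo = 1e-13
        hi = 1.0
        root = brentq(lambda u: g(u) - u, lo, hi, xtol=tol, rtol=8.9e-16)
        return float(root)
    # f >= 1: u = 0 is the only nonnegative fixed point, but plain
    # iteration converges only algebraically when c -> 1; Newton on
    # h(u) = g(u) - u converges fast (and still quenches the c = 1
    # double root by halving)
    u = 0.5
    for _ in range(max_iter):
        hu = g(u) - u
        dh = c / (1.0 + c * u) ** 2 - 1.0
        if dh == 0.0:
            break
        u_new = min(max(u - hu / dh, 0.0), 1.0)
        if abs(u_new - u) < tol:
            return u_new
        u = u_new
    if abs(g(u) - u) < math.sqrt(tol):
        return u
    raise RuntimeError("self-consistent iteration did not converge")


@dataclass
class MC1DResult:
    """Ensemble velocity estimate from the 1D Monte Carlo."""

    mean_velocity: float
    sd: float
    sem: float
    n_runs: int
    v0: float

    @property
    def reduced(self) -> float:
        """Velocity in units of v0."""
        return self.mean_velocity / self.v0


def mc_1d_simulate(
    threshold: float,
    memory_time: float,
    molecular_rate: float,
    mean_cargo: float,
    hill: float,
    v0: float = 3.4 / 60.0,
    dt_cell: float = 1.0,
    total_time: float = 1440.0,
    n_runs: int = 400,
    seed: int = 0,
    initial_separation: float = 0.0,
    alpha_mode: str = "poisson",
) -> MC1DResult:
    """Direct 1D Monte Carlo of the reduced leader-follower model.

    The leader at l0 + v0 t drops immobile point exosomes (Poisson counts
    at rate nu/nbar per step) at its current position; the follower steps
    +/-v0*dt with P(right) = (1/2+M)/(1+M), absorbing every live exosome in
    the interval swept by its step (endpoints inclusive).  Detections are
    registered at the end of the step; memory decays by exp(-dt/tau)
    between decisions.  ``alpha_mode="mean"`` replaces each realized
    activation by the mean-cargo activation abar, isolating that
    approximation of the closed-form derivation.

    The leader starts on the follower (l0 = 0) by default: leader and
    follower share the same speed, so with a positive head start the
    follower could never reach the trail at all — the theory describes the
    walk *along* the trail.  The default step (1 min) is well below the
    default memory time so the discrete walk probes the quasi-continuous
    regime assumed by the closed form.
    """
    if alpha_mode not in ("poisson", "mean"):
        raise ValueError("alpha_mode must be 'poisson' or 'mean'")
    if initial_separation < 0:
        raise ValueError("the leader cannot start behind the follower")
    n_steps = round(total_time / dt_cell)
    decay = math.exp(-dt_cell / memory_time)
    abar = float(
        activation_array(np.array([mean_cargo]), threshold, hill)[0]
    )
    drop_rate = molecular_rate * dt_cell / mean_cargo
    step = v0 * dt_cell
    velocities = np.empty(n_runs)
    for run in range(n_runs):
        rng = np.random.default_rng(seed + run)
        counts = rng.poisson(drop_rate, n_steps)
        n_total = int(counts.sum())
        birth_step = np.repeat(np.arange(n_steps), counts)
        # dropped at the leader's position at the start of the step
        pos = initial_separation + v0 * dt_cell * birth_step
        if alpha_mode == "poisson":
            alpha = activation_array(rng.poisson(mean_cargo, n_total), threshold, hill)
        else:
            alpha = np.full(n_total, abar)
        alive = np.ones(n_total, dtype=bool)
        born = np.cumsum(counts)
        xf = 0.0
        M = 0.0
        for k in range(n_steps):
            M *= decay
            direction = 1.0 if rng.random() < (0.5 + M) / (1.0 + M) else -1.0
            x_new = xf + direction * step
            lo, hi = (xf, x_new) if x_new >= xf else (x_new, xf)
            nb = int(born[k])
            i0 = int(np.searchsorted(pos[:nb], lo, side="left"))
            i1 = int(np.searchsorted(pos[:nb], hi, side="right"))
            if i1 > i0:
                hit = np.flatnonzero(alive[i0:i1]) + i0
                if hit.size:
                    M += float(alpha[hit].sum())
                    alive[hit] = False
            xf = x_new
        velocities[run] = xf / total_time
    sd = float(np.std(velocities, ddof=1)) if n_runs > 1 else 0.0
    return MC1DResult(
        mean_velocity=float(np.mean(velocities)),
        sd=sd,
        sem=sd / math.sqrt(n_runs),
        n_runs=n_runs,
        v0=v0,
    )
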