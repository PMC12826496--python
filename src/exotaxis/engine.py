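"""Two-timescale 2D engine: leader, exosome field, follower, ensembles.

The leader starts ``l0`` ahead of the follower (which starts at the origin)
and moves in +x at speed v0.  Cell decisions happen every ``dt_cell``
minutes; within each cell step the exosome field is advanced on the finer
``dt_exo`` grid (leader update -> secretion -> diffusion -> wall reflection
-> degradation -> detection against the follower's current, piecewise-
constant position).  At each cell tick the follower reads out its memory,
samples a direction (biased with probability M/(1+M)) and takes one step of
length v0 * dt_cell.

Two numerically equivalent paths exist: ``method="fast"`` (compiled kernel
with far-field jump acceleration; the production path) and
``method="reference"`` (the per-substep numpy path built from the public
field/memory operations; used for cross-validation and event-level
inspection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from ._kernel import JUMP_EPS, JUMP_TABLE_RES, get_jump_tables, window_kernel
from .config import ScenarioConfig
from .field import ExosomeField, degrade_step, detect_and_absorb, diffuse_step, reflect_walls, secrete
from .memory import (
    MemoryAccumulators,
    activation_array,
    decay_to,
    readout,
    register_event,
    sample_direction,
)

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "SweepResult",
    "run_single",
    "run_ensemble",
    "sweep",
    "mean_velocity",
    "cargo_scaled_diffusivity",
    "SWEEPABLE_PARAMETERS",
]

#: recognized sweep-parameter names (canonical name -> config field), with
#: the field-notation aliases accepted by :func:`sweep`
SWEEPABLE_PARAMETERS = {
    "mean_cargo": "mean_cargo",
    "nbar": "mean_cargo",
    "n_bar": "mean_cargo",
    "diffusivity": "diffusivity",
    "D": "diffusivity",
    "molecular_rate": "molecular_rate",
    "nu": "molecular_rate",
    "memory_time": "memory_time",
    "tau": "memory_time",
    "degradation_time": "degradation_time",
    "T_deg": "degradation_time",
    "hill": "hill",
    "H": "hill",
    "initial_separation": "initial_separation",
    "l0": "initial_separation",
    "wall_half_width": "wall_half_width",
    "L": "wall_half_width",
    "threshold": "threshold",
    "K": "threshold",
}


def cargo_scaled_diffusivity(mean_cargo: float, D0: float, mean_cargo_ref: float) -> float:
    """Stokes-Einstein cargo scaling D(nbar) = D0 (nbar0/nbar)^(1/3).

    If exosome volume scales with cargo load, radius scales as nbar^(1/3)
    and diffusivity as nbar^(-1/3).
    """
    if mean_cargo <= 0 or D0 <= 0 or mean_cargo_ref <= 0:
        raise ValueError("all arguments must be positive")
    return D0 * (mean_cargo_ref / mean_cargo) ** (1.0 / 3.0)


@dataclass
class Trajectory:
    """One follower path, sampled at cell ticks."""

    times: np.ndarray
    follower: np.ndarray  # (n_ticks + 1, 2)
    detections: np.ndarray  # detections per cell step
    live_counts: np.ndarray  # live exosomes at each cell tick
    seed: int
    leader: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.follower[0, 0] != 0.0 or self.follower[0, 1] != 0.0:
            raise ValueError("the follower must start at the origin")


def mean_velocity(trajectory: Trajectory) -> float:
    """Net drift along the leader's heading: (x_f(T) - x_f(0)) / T."""
    T = trajectory.times[-1] - trajectory.times[0]
    if T <= 0:
        raise ValueError("total time must be positive")
    return float(trajectory.follower[-1, 0] - trajectory.follower[0, 0]) / T


@dataclass
class EnsembleSummary:
    """Ensemble mean follower velocity with its sampling uncertainty."""

    mean_velocity: float
    sd: float
    sem: float
    n_runs: int
    base_seed: int
    parameter: str | None = None
    value: float | None = None
    velocities: np.ndarray = dc_field(default_factory=lambda: np.empty(0))


@dataclass
class SweepResult:
    """A parameter sweep: per-value summaries, a tidy table, and the grid
    argmax of the mean velocity (ties broken toward the smaller value,
    reported with its one-grid-step neighbourhood)."""

    parameter: str
    values: list
    summaries: list
    table: pd.DataFrame
    argmax_value: float
    argmax_index: int
    argmax_bracket: tuple

    def summary_for(self, value) -> EnsembleSummary:
        return self.summaries[self.values.index(value)]


# ---------------------------------------------------------------------------
# fast path


def _normals_buffer_size(n_particles: int, n_sub: int) -> int:
    # capped at 512k floats (2 MB) so the buffer stays cache-resident
    size = max(1 << 14, min(1 << 19, 8 * n_particles))
    return max(size, 4 * n_sub + 16)


def _run_single_fast(config: ScenarioConfig, seed: int, record_leader: bool) -> Trajectory:
    # two independent child streams: one for structure/decisions, one for
    # the high-volume displacement noise (SFC64: fastest bulk generator)
    ss_decisions, ss_noise = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_decisions)
    rng_noise = np.random.Generator(np.random.SFC64(ss_noise))
    dt = config.dt_exo
    n_sub = config.substeps_per_cell_step
    n_win = config.n_cell_steps
    n_sub_total = n_sub * n_win
    v0 = config.v0
    tau = config.memory_time
    a2 = config.capture_radius**2

    # all births, cargos and activations are drawn up front
    counts = rng.poisson(config.molecular_rate * dt / config.mean_cargo, n_sub_total)
    birth_sub = np.repeat(np.arange(n_sub_total, dtype=np.int64), counts)
    cargo = rng.poisson(config.mean_cargo, birth_sub.size)
    if config.drop_zero_cargo:
        keep = cargo > 0
        birth_sub, cargo = birth_sub[keep], cargo[keep]
    alpha = activation_array(cargo, config.threshold, config.hill)
    n_total = birth_sub.size
    px = config.initial_separation + v0 * (birth_sub + 1.0) * dt
    py = np.zeros(n_total)
    alive = np.ones(n_total, dtype=np.int8)
    if config.per_exosome_diffusivity:
        d_i = config.D0 * (config.mean_cargo_ref / np.maximum(cargo, 1)) ** (1.0 / 3.0)
        sig = np.sqrt(2.0 * d_i * dt)
    else:
        sig = np.full(n_total, math.sqrt(2.0 * config.effective_diffusivity() * dt))

    has_wall = config.wall_half_width is not None
    wall_L = config.wall_half_width if has_wall else 0.0
    p_deg = 0.0 if config.degradation_time is None else dt / config.degradation_time
    if has_wall:
        jump_eps_log = 0.0
        thr2 = np.zeros_like(sig)
    else:
        jump_eps_log = math.log(1.0 / JUMP_EPS)
        thr = config.capture_radius + sig * math.sqrt(2.0 * jump_eps_log)
        thr2 = thr * thr

    k_tab, sqrtk_tab = get_jump_tables()
    buf_n = _normals_buffer_size(n_total, n_sub)
    normals = rng_noise.standard_normal(buf_n, dtype=np.float32)
    nc = 0
    buf_u = max(1 << 12, 2 * n_sub + 16)
    uniforms = rng.random(buf_u) if p_deg > 0.0 else np.empty(1)
    uc = 0

    born_by_window = np.cumsum(counts)  # particles born by each substep
    if config.drop_zero_cargo:
        # birth_sub stays sorted; recompute the per-window particle counts
        born_by_window = np.searchsorted(birth_sub, np.arange(1, n_sub_total + 1))

    decay_win = math.exp(-config.dt_cell / tau)
    M = S = C = 0.0
    fx = fy = 0.0
    times = np.empty(n_win + 1)
    fpos = np.empty((n_win + 1, 2))
    lead = np.empty((n_win + 1, 2)) if record_leader else None
    det_counts = np.zeros(n_win, dtype=np.int64)
    live_counts = np.zeros(n_win, dtype=np.int64)
    times[0] = 0.0
    fpos[0] = 0.0
    if lead is not None:
        lead[0] = (config.initial_separation, 0.0)

    cull2 = None
    if config.cull_distance is not None:
        cull2 = config.cull_distance**2

    for w in range(n_win):
        win_start = w * n_sub
        n_part = int(born_by_window[win_start + n_sub - 1])
        acc_m = acc_s = acc_c = 0.0
        ndet = 0
        start_i = 0
        while True:
            status, start_i, nc, uc, acc_m, acc_s, acc_c, ndet = window_kernel(
                px, py, alive, alpha, sig, thr2, birth_sub, n_part, start_i,
                win_start, n_sub, fx, fy, a2, dt, tau, p_deg,
                1 if has_wall else 0, wall_L, jump_eps_log,
                k_tab, sqrtk_tab, float(JUMP_TABLE_RES),
                normals, nc, uniforms, uc, acc_m, acc_s, acc_c, ndet,
            )
            if status == 0:
                break
            if status == 1:
                normals = rng_noise.standard_normal(buf_n, dtype=np.float32)
                nc = 0
            else:
                uniforms = rng.random(buf_u)
                uc = 0
        # memory at the cell tick: decay last tick's sums, add this window's
        # (already discounted to the window end inside the kernel)
        M = M * decay_win + acc_m
        S = S * decay_win + acc_s
        C = C * decay_win + acc_c
        mean_angle = math.atan2(S, C) if (S != 0.0 or C != 0.0) else None
        theta = sample_direction(M, mean_angle, rng)
        fx += v0 * config.dt_cell * math.cos(theta)
        fy += v0 * config.dt_cell * math.sin(theta)
        if has_wall:
            while fy > wall_L or fy < -wall_L:
                fy = 2.0 * wall_L - fy if fy > wall_L else -2.0 * wall_L - fy
        if cull2 is not None:
            sl = slice(0, n_part)
            far = (px[sl] - fx) ** 2 + (py[sl] - fy) ** 2 > cull2
            alive[sl][far] = 0
        times[w + 1] = (w + 1) * config.dt_cell
        fpos[w + 1] = (fx, fy)
        if lead is not None:
            lead[w + 1] = (config.initial_separation + v0 * times[w + 1], 0.0)
        det_counts[w] = ndet
        live_counts[w] = int(np.count_nonzero(alive[:n_part]))

    return Trajectory(
        times=times,
        follower=fpos,
        detections=det_counts,
        live_counts=live_counts,
        seed=seed,
        leader=lead,
    )


# ---------------------------------------------------------------------------
# reference path


def _run_single_reference(config: ScenarioConfig, seed: int, record_leader: bool) -> Trajectory:
    if config.per_exosome_diffusivity or config.drop_zero_cargo or config.cull_distance:
        raise NotImplementedError(
            "efficiency variants are only available on the fast path"
        )
    rng = np.random.default_rng(seed)
    dt = config.dt_exo
    n_sub = config.substeps_per_cell_step
    n_win = config.n_cell_steps
    sp = config.secretion_params()
    rp = config.response_params()
    D = config.effective_diffusivity()
    T_deg = config.degradation_time_or_inf
    v0 = config.v0
    l0 = config.initial_separation
    L = config.wall_half_width

    fld = ExosomeField()
    acc = MemoryAccumulators()
    follower = np.zeros(2)
    times = np.empty(n_win + 1)
    fpos = np.empty((n_win + 1, 2))
    lead = np.empty((n_win + 1, 2)) if record_leader else None
    det_counts = np.zeros(n_win, dtype=np.int64)
    live_counts = np.zeros(n_win, dtype=np.int64)
    times[0] = 0.0
    fpos[0] = 0.0
    if lead is not None:
        lead[0] = (l0, 0.0)

    for w in range(n_win):
        ndet = 0
        for j in range(n_sub):
            t = (w * n_sub + j + 1) * dt
            leader = np.array([l0 + v0 * t, 0.0])
            secrete(leader, sp, dt, t, rng, out=fld)
            diffuse_step(fld, D, dt, rng)
            if L is not None:
                follower = reflect_walls(fld, follower, L)
            degrade_step(fld, T_deg, dt, rng)
            events = detect_and_absorb(fld, follower, config.capture_radius, t, rp)
            for e in events:
                acc = register_event(acc, e, rp.memory_time)
            ndet += len(events)
        tick = (w + 1) * config.dt_cell
        M, mean_angle = readout(acc, tick, rp.memory_time)
        acc = decay_to(acc, tick, rp.memory_time)
        acc.check()
        theta = sample_direction(M, mean_angle, rng)
        follower = follower + v0 * config.dt_cell * np.array(
            [math.cos(theta), math.sin(theta)]
        )
        if L is not None:
            follower = reflect_walls(fld, follower, L)
        times[w + 1] = tick
        fpos[w + 1] = follower
        if lead is not None:
            lead[w + 1] = (l0 + v0 * tick, 0.0)
        det_counts[w] = ndet
        live_counts[w] = fld.n_alive

    return Trajectory(
        times=times,
        follower=fpos,
        detections=det_counts,
        live_counts=live_counts,
        seed=seed,
        leader=lead,
    )


def run_single(
    config: ScenarioConfig,
    seed: int,
    method: str = "fast",
    record_leader: bool = False,
) -> Trajectory:
    """Run one realization; bit-reproducible for a given (config, seed)."""
    if method == "fast":
        return _run_single_fast(config, seed, record_leader)
    if method == "reference":
        return _run_single_reference(config, seed, record_leader)
    raise ValueError("method must be 'fast' or 'reference'")


def run_ensemble(config: ScenarioConfig, method: str = "fast") -> EnsembleSummary:
    """Run n_runs independent realizations with seeds base_seed + i.

    The common-random-numbers seed policy means sweeps that reuse the same
    base_seed differ between grid points only through the swept parameter.
    """
    if config.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    velocities = np.empty(config.n_runs)
    for i in range(config.n_runs):
        traj = run_single(config, config.base_seed + i, method=method)
        velocities[i] = mean_velocity(traj)
    sd = float(np.std(velocities, ddof=1)) if config.n_runs > 1 else 0.0
    return EnsembleSummary(
        mean_velocity=float(np.mean(velocities)),
        sd=sd,
        sem=sd / math.sqrt(config.n_runs),
        n_runs=config.n_runs,
        base_seed=config.base_seed,
        velocities=velocities,
    )


def sweep(
    config: ScenarioConfig,
    parameter_name: str,
    values,
    method: str = "fast",
) -> SweepResult:
    """Run one ensemble per grid value of a recognized parameter.

    Every grid point reuses the run-seed sequence base_seed + i (common
    random numbers).  The argmax of the mean velocity is reported at the
    grid resolution: ties break toward the smaller value and the one-step
    bracket (neighbouring grid values) is attached.
    """
    if parameter_name not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"unknown sweep parameter {parameter_name!r}; recognized: "
            f"{sorted(set(SWEEPABLE_PARAMETERS))}"
        )
    fld = SWEEPABLE_PARAMETERS[parameter_name]
    values = list(values)
    summaries = []
    for v in values:
        v_cfg = None if (fld == "degradation_time" and v is not None and math.isinf(v)) else v
        cfg = config.model_copy(update={fld: v_cfg})
        cfg = ScenarioConfig.model_validate(cfg.model_dump())
        s = run_ensemble(cfg, method=method)
        s.parameter = fld
        s.value = v
        summaries.append(s)
    means = [s.mean_velocity for s in summaries]
    best = 0
    for i, m in enumerate(means):
        if m > means[best]:
            best = i
    bracket = (
        values[max(best - 1, 0)],
        values[best],
        values[min(best + 1, len(values) - 1)],
    )
    table = pd.DataFrame(
        {
            "parameter": fld,
            "value": [
                float(v) if v is not None else math.nan for v in values
            ],
            "mean_velocity": means,
            "sd": [s.sd for s in summaries],
            "sem": [s.sem for s in summaries],
            "n_runs": [s.n_runs for s in summaries],
            "base_seed": [s.base_seed for s in summaries],
        }
    )
    return SweepResult(
        parameter=fld,
        values=values,
        summaries=summaries,
        table=table,
        argmax_value=values[best],
        argmax_index=best,
        argmax_bracket=bracket,
    )
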