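"""Compiled inner loop of the 2D engine.

One call advances a batch of exosomes through (part of) a single cell-step
window, during which the follower is fixed at (fx, fy).  Per substep each
live particle takes a Gaussian step of per-axis scale sig[i], optionally
reflects off walls at y = +/-L, degrades with probability p_deg, and is
absorbed if it lies within the capture radius of the follower; an absorbed
particle's activation is accumulated into the (M, S, C) deltas, discounted
by the memory kernel from its detection time to the end of the window.

Far-field acceleration
----------------------
A particle at distance d > a from the follower may traverse k substeps in
one Gaussian jump of per-axis scale sig*sqrt(k), skipping the k-1
intermediate detection checks (the jump endpoint is always checked).  Any
skipped position inside the capture disc would require a displacement of
magnitude r = d - a, and for the isotropic Gaussian walk

    P(some W_j, j<k, has |W_j| >= r) <= (k-1) exp(-r^2 / (2 (k-1) sig^2)),

a union bound over the exact per-step radial tail.  The kernel picks the
largest k keeping this below eps (default 1e-5), so the probability that a
jump skips a would-be detection check is at most eps; with O(10^6) jumps
per run the expected number of delayed checks is orders of magnitude below
the detection count, and a delayed particle remains live and detectable.
Setting jump_eps_log <= 0 disables jumping (always done when walls are
active, since endpoint folding does not commute with intermediate checks).

Randomness is consumed from caller-provided buffers (float32 standard
normals, float64 uniforms).  The kernel returns early at a particle
boundary when a buffer runs low (status 1: normals, status 2: uniforms) so
the caller can refill and resume; status 0 means the batch is complete.
"""

import math

import numba
import numpy as np

__all__ = [
    "window_kernel",
    "JUMP_EPS",
    "jump_threshold_distance",
    "jump_table",
    "max_admissible_jump",
]

#: tail-probability budget per far-field jump
JUMP_EPS = 1e-5


def jump_threshold_distance(sigma: float, capture_radius: float, eps: float = JUMP_EPS) -> float:
    """Minimum distance from the follower at which a 2-substep jump is
    admissible: a + sigma * sqrt(2 ln(1/eps))."""
    return capture_radius + sigma * math.sqrt(2.0 * math.log(1.0 / eps))


def max_admissible_jump(rho: float, eps: float = JUMP_EPS) -> int:
    """Largest k with (k-1) exp(-rho^2/(2(k-1))) <= eps, rho = r/sigma.

    This is the per-jump guarantee: among the k-1 skipped intermediate
    positions of a standard 2D Gaussian walk, the probability that any lies
    within rho of the origin is at most eps.
    """
    if rho <= 0.0:
        return 1
    lie = math.log(1.0 / eps)
    q = 0.5 * rho * rho
    m = q / lie
    if m <= 1.0:
        return 1
    # one damped refinement; f(m) = m exp(-q/m) is increasing, so the
    # refined m stays on the admissible side (see note in module docstring)
    m = q / (math.log(m) + lie)
    return int(m) + 1 if m >= 1.0 else 1


#: lookup resolution: index = int(JUMP_TABLE_RES * r / sigma)
JUMP_TABLE_RES = 4
_JUMP_TABLE_SIZE = 8192


def jump_table(
    eps: float = JUMP_EPS, res: int = JUMP_TABLE_RES, size: int = _JUMP_TABLE_SIZE
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated (k, sqrt(k)) over quantized rho = r/sigma.

    Entry i holds the admissible jump for rho = i/res, a floor for every
    rho in the bucket [i/res, (i+1)/res), so table use is conservative.
    """
    k = np.array([max_admissible_jump(i / res, eps) for i in range(size)],
                 dtype=np.int64)
    return k, np.sqrt(k.astype(np.float64))


_K_TAB, _SQRTK_TAB = jump_table()


def get_jump_tables() -> tuple[np.ndarray, np.ndarray]:
    return _K_TAB, _SQRTK_TAB


@numba.njit(cache=True, nogil=True, fastmath=True)
def window_kernel(
    px,
    py,
    alive,
    alpha,
    sig,
    thr2,
    birth_sub,
    n_part,
    start_i,
    win_start,
    n_sub,
    fx,
    fy,
    a2,
    dt,
    tau,
    p_deg,
    has_wall,
    wall_L,
    jump_eps_log,
    k_tab,
    sqrtk_tab,
    tab_res,
    normals,
    nc,
    uniforms,
    uc,
    acc_m,
    acc_s,
    acc_c,
    ndet,
):  # pragma: no cover - exercised via the engine
    a_ = math.sqrt(a2)
    need_n = 2 * n_sub + 4
    need_u = n_sub + 2
    inv_tau = 1.0 / tau
    lie = jump_eps_log  # ln(1/eps); <= 0 disables jumps
    tab_n = k_tab.shape[0]
    for i in range(start_i, n_part):
        if alive[i] == 0:
            continue
        if nc > normals.shape[0] - need_n:
            return 1, i, nc, uc, acc_m, acc_s, acc_c, ndet
        if p_deg > 0.0 and uc > uniforms.shape[0] - need_u:
            return 2, i, nc, uc, acc_m, acc_s, acc_c, ndet
        s = birth_sub[i] - win_start
        if s < 0:
            s = 0
        x = px[i]
        y = py[i]
        sg = sig[i]
        am = alpha[i]
        dx = x - fx
        dy = y - fy
        d2 = dx * dx + dy * dy
        if sg == 0.0:
            # immobile particle: fixed geometry for the whole window
            if d2 <= a2:
                s += 1
                if p_deg > 0.0:
                    if uniforms[uc] < p_deg:
                        uc += 1
                        alive[i] = 0
                        continue
                    uc += 1
                theta = 0.0
                if dx != 0.0 or dy != 0.0:
                    theta = math.atan2(dy, dx)
                w = math.exp(-(n_sub - s) * dt * inv_tau)
                acc_m += am * w
                acc_s += am * w * math.sin(theta)
                acc_c += am * w * math.cos(theta)
                ndet += 1
                alive[i] = 0
            elif p_deg > 0.0:
                surv = (1.0 - p_deg) ** (n_sub - s)
                if uniforms[uc] >= surv:
                    alive[i] = 0
                uc += 1
            continue
        t2 = thr2[i]
        res_osg = tab_res / sg
        while s < n_sub:
            k = 1
            scale = sg
            if lie > 0.0 and d2 > t2:
                idx = int((math.sqrt(d2) - a_) * res_osg)
                if idx >= tab_n:
                    idx = tab_n - 1
                kt = k_tab[idx]
                krem = n_sub - s
                if kt < krem:
                    k = kt
                    scale = sg * sqrtk_tab[idx]
                elif krem >= 2:
                    k = krem
                    scale = sg * math.sqrt(float(krem))
            x += scale * normals[nc]
            y += scale * normals[nc + 1]
            nc += 2
            s += k
            if k == 1 and has_wall == 1:
                while y > wall_L or y < -wall_L:
                    if y > wall_L:
                        y = 2.0 * wall_L - y
                    else:
                        y = -2.0 * wall_L - y
            if p_deg > 0.0:
                if k == 1:
                    dead = uniforms[uc] < p_deg
                else:
                    dead = uniforms[uc] >= (1.0 - p_deg) ** k
                uc += 1
                if dead:
                    alive[i] = 0
                    break
            dx = x - fx
            dy = y - fy
            d2 = dx * dx + dy * dy
            if d2 <= a2:
                theta = 0.0
                if dx != 0.0 or dy != 0.0:
                    theta = math.atan2(dy, dx)
                w = math.exp(-(n_sub - s) * dt * inv_tau)
                acc_m += am * w
                acc_s += am * w * math.sin(theta)
                acc_c += am * w * math.cos(theta)
                ndet += 1
                alive[i] = 0
                break
        px[i] = x
        py[i] = y
    return 0, n_part, nc, uc, acc_m, acc_s, acc_c, ndet
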