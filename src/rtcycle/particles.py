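"""Stochastic particle-level simulation of the three-state cell cycle.

An independent route to the displacement moments: instead of solving the
density equations, simulate the underlying jump-drift-diffusion process
cell by cell.  A right/left mover drifts at +-v, diffuses with diffusivity
D, and after an exponential waiting time settles (rate lambda_s), reverses
(lambda_e) or dies (mu); a settled cell waits an exponential time with
rate lambda_d and is then replaced by one right- and one left-moving
daughter at its position.  Starting from a single settled cell at the
origin, ensemble ratios E[sum_cells x^n] / E[#cells] estimate the
density-weighted moments <(x - x0)^n>, with standard errors from the
per-ancestor spread (delta method for the ratio estimator).

This module is deliberately independent of :mod:`rtcycle.spectral`; the two
are cross-validated in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParams, ParameterError

__all__ = ["MCMoments", "moments_mc"]

_STACK_CAP = 8192


@njit(cache=False)
def _simulate_ancestors(n_anc, obs, ls, ld, le, mu, vp, vmn, D, seed,
                        tot_acc, set_acc):
    """Accumulate per-ancestor sums of x^1..x^4 and counts at each obs time.

    tot_acc/set_acc have shape (n_anc, n_obs, 5): columns x, x^2, x^3, x^4,
    count — for all alive cells and for settled cells respectively.
    Returns 0 on success, 1 on stack overflow (raise in the caller).
    """
    np.random.seed(seed)
    n_obs = obs.shape[0]
    t_max = obs[n_obs - 1]
    stack_state = np.empty(_STACK_CAP, dtype=np.int8)  # 0=right, 1=settled, 2=left
    stack_x = np.empty(_STACK_CAP)
    stack_t = np.empty(_STACK_CAP)
    mover_rate = ls + le + mu
    for a in range(n_anc):
        top = 0
        stack_state[0] = 1
        stack_x[0] = 0.0
        stack_t[0] = 0.0
        top = 1
        while top > 0:
            top -= 1
            state = stack_state[top]
            x = stack_x[top]
            t = stack_t[top]
            alive = True
            while alive:
                rate = ld if state == 1 else mover_rate
                if rate > 0.0:
                    tau = -math.log(np.random.random()) / rate
                else:
                    tau = 2.0 * t_max + 1.0
                t_event = t + tau
                t_seg_end = t_event if t_event < t_max else t_max
                # record observations inside (t, t_seg_end]
                for io in range(n_obs):
                    to = obs[io]
                    if to <= t or to > t_seg_end:
                        continue
                    if state != 1:
                        dt_ = to - t
                        v = vp if state == 0 else -vmn
                        x += v * dt_ + math.sqrt(2.0 * D * dt_) * np.random.standard_normal()
                        t = to
                    tot_acc[a, io, 0] += x
                    tot_acc[a, io, 1] += x * x
                    tot_acc[a, io, 2] += x * x * x
                    tot_acc[a, io, 3] += x * x * x * x
                    tot_acc[a, io, 4] += 1.0
                    if state == 1:
                        set_acc[a, io, 0] += x
                        set_acc[a, io, 1] += x * x
                        set_acc[a, io, 2] += x * x * x
                        set_acc[a, io, 3] += x * x * x * x
                        set_acc[a, io, 4] += 1.0
                if t_event >= t_max:
                    alive = False
                    break
                # advance to the event
                if state != 1:
                    dt_ = t_event - t
                    v = vp if state == 0 else -vmn
                    x += v * dt_ + math.sqrt(2.0 * D * dt_) * np.random.standard_normal()
                t = t_event
                if state == 1:
                    # doubling: replaced by a right- and a left-moving daughter
                    if top + 2 > _STACK_CAP:
                        return 1
                    stack_state[top] = 0
                    stack_x[top] = x
                    stack_t[top] = t
                    top += 1
                    stack_state[top] = 2
                    stack_x[top] = x
                    stack_t[top] = t
                    top += 1
                    alive = False
                else:
                    u = np.random.random() * mover_rate
                    if u < ls:
                        state = 1
                    elif u < ls + le:
                        state = 0 if state == 2 else 2
                    else:
                        alive = False  # death
    return 0


@dataclass(frozen=True)
class MCMoments:
    """Monte-Carlo displacement moments with standard errors.

    ``values``/``errors`` have shape (n_times, 4) for moment orders 1..4;
    ``counts`` is the mean number of (selected) cells per ancestor at each
    time — the normalization of the ratio estimator.
    """

    selector: str
    times: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    counts: np.ndarray
    n_ancestors: int


def moments_mc(
    params: ModelParams,
    times,
    n_ancestors: int = 100_000,
    seed: int = 12345,
    selector: str = "total",
) -> MCMoments:
    """Displacement moments of orders 1..4 from a particle-level simulation.

    The initial condition is one settled cell at the origin per ancestor
    (the delta initial condition of the spectral route).  Moments are the
    ratio estimators sum(x^n over cells) / sum(count) across ancestors;
    errors are 1-sigma via the delta method, so two estimates should agree
    within a few combined sigmas.
    """
    if selector not in ("total", "settled"):
        raise ParameterError("selector must be 'total' or 'settled'")
    if not params.interactions.free:
        raise ParameterError("the particle oracle simulates free cells only")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ParameterError("times must be positive and strictly increasing")
    r, tr = params.rates, params.transport
    tot = np.zeros((n_ancestors, times.size, 5))
    setl = np.zeros((n_ancestors, times.size, 5))
    status = _simulate_ancestors(
        n_ancestors, times, r.lambda_s, r.lambda_d, r.lambda_e, r.mu,
        tr.v_plus, tr.v_minus, tr.D, seed, tot, setl,
    )
    if status != 0:
        raise RuntimeError("particle stack overflow: population grew beyond capacity")
    acc = tot if selector == "total" else setl
    vals = np.empty((times.size, 4))
    errs = np.empty((times.size, 4))
    cnts = np.empty(times.size)
    M = float(n_ancestors)
    for it in range(times.size):
        n = acc[:, it, 4]
        nbar = n.mean()
        cnts[it] = nbar
        if nbar == 0:
            raise ParameterError(f"no {selector} cells alive at t={times[it]:g}")
        for order in range(1, 5):
            s = acc[:, it, order - 1]
            sbar = s.mean()
            ratio = sbar / nbar
            # delta method for var(sbar/nbar) over independent ancestors
            cov = np.cov(s, n, ddof=1)
            var = (cov[0, 0] - 2.0 * ratio * cov[0, 1] + ratio**2 * cov[1, 1]) / (M * nbar**2)
            vals[it, order - 1] = ratio
            errs[it, order - 1] = math.sqrt(max(var, 0.0))
    return MCMoments(
        selector=selector, times=times, values=vals, errors=errs,
        counts=cnts, n_ancestors=n_ancestors,
    )
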