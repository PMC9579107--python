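"""Classification of long-time PDE solutions and the non-equilibrium state diagram.

A long-time solution of the spatial model is either spatially uniform, a
static density wave (equal running speeds), or a traveling wave; the wave
speed v_s is reported in units of sqrt(D*lambda_e).  Scanning the
(v_r, v_m) plane of reduced speed difference and dimensionless maximum
speed and bisecting on the verdict yields the wave/no-wave transition
line, summarized — like its linear-stability counterpart — by a quadratic
least-squares fit v_m^f(v_r) = c0 + c1 v_r + c2 v_r^2.

Finite-horizon classification.  Near the transition the single unstable
domain mode grows at a rate that vanishes linearly, so no fixed-length run
can push its amplitude over a fixed threshold arbitrarily close to onset.
Converged or saturated runs are therefore classified by the relative
amplitude threshold directly; unconverged runs by the sign of the fitted
exponential growth rate of the pattern amplitude over the late part of the
run (positive growth will saturate into a wave given time).  Both
thresholds are configuration keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import ModelParams, ParameterError, Transport, speeds_from_vm_vr
from .pde import (
    FieldState,
    Grid,
    SolverConfig,
    Trajectory,
    add_gaussian_noise,
    init_uniform_stationary,
    integrate,
)
from .stability import SeparatrixFit, quadratic_fit

__all__ = [
    "PatternVerdict",
    "StateDiagram",
    "classify_pattern",
    "wave_speed",
    "state_diagram",
]


@dataclass(frozen=True)
class PatternVerdict:
    """Outcome of classifying one long-time solution.

    ``kind`` is 'uniform', 'static_wave' or 'traveling_wave'; ``amplitude``
    the relative peak-to-peak modulation of the total density on the final
    snapshot; ``v_s`` the dimensionless wave speed (signed; None for
    uniform states); ``growth_rate`` the fitted late-time exponential rate
    of the amplitude (diagnostic, None when not computed).
    """

    kind: str
    amplitude: float
    v_s: float | None = None
    growth_rate: float | None = None
    conclusive: bool = True


def _periodic_shift(a: np.ndarray, b: np.ndarray, L: float) -> float:
    """Shift d such that b(x) ~ a(x - d), via the periodic cross-correlation peak.

    Sub-grid precision from a parabolic interpolation of the correlation
    around its maximum; profiles are mean-removed and normalized first.
    Returns d in length units, wrapped to (-L/2, L/2].
    """
    n = a.size
    scale = max(float(np.abs(a).max()), float(np.abs(b).max()), 1e-300)
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = np.linalg.norm(a), np.linalg.norm(b)
    if sa <= 1e-12 * scale * math.sqrt(n) or sb <= 1e-12 * scale * math.sqrt(n):
        raise ParameterError("wave speed undefined for a flat profile")
    corr = np.fft.irfft(np.fft.rfft(b) * np.conj(np.fft.rfft(a)), n=n)
    i = int(np.argmax(corr))
    # parabolic refinement on the periodic triple (i-1, i, i+1)
    c0, c1, c2 = corr[(i - 1) % n], corr[i], corr[(i + 1) % n]
    denom = c0 - 2.0 * c1 + c2
    frac = 0.0 if denom == 0 else 0.5 * (c0 - c2) / denom
    shift = (i + frac) * (L / n)
    if shift > L / 2.0:
        shift -= L
    return float(shift)


def wave_speed(
    trajectory: Trajectory,
    D: float | None = None,
    lambda_e: float | None = None,
    n_pairs: int = 4,
    species: int | None = None,
) -> float:
    """Dimensionless wave speed from late-time snapshot pairs.

    The shift between consecutive late snapshots of the total density
    profile (or a single species if ``species`` is 0, 1 or 2) is estimated
    by periodic cross-correlation with parabolic sub-grid interpolation,
    converted to a speed, averaged over pairs and divided by
    sqrt(D*lambda_e).  The snapshot stride must be small enough that the
    per-pair displacement stays below half a domain (no unwrapping is
    attempted beyond that).
    """
    if trajectory.states.shape[0] < 2:
        raise ParameterError("wave speed needs at least two snapshots")
    D = trajectory.params.transport.D if D is None else D
    lambda_e = trajectory.params.rates.lambda_e if lambda_e is None else lambda_e
    if D <= 0 or lambda_e <= 0:
        raise ParameterError("wave speed normalization requires D > 0 and lambda_e > 0")
    L = trajectory.grid.L
    n_avail = trajectory.states.shape[0] - 1
    n_use = min(n_pairs, n_avail)
    speeds = []
    for j in range(n_use):
        i1 = trajectory.states.shape[0] - 1 - n_use + j
        i2 = i1 + 1
        prof = (lambda s: s.sum(axis=0) if species is None else s[species])
        a = prof(trajectory.states[i1])
        b = prof(trajectory.states[i2])
        dtau = float(trajectory.times[i2] - trajectory.times[i1])
        if dtau <= 0:
            continue
        speeds.append(_periodic_shift(a, b, L) / dtau)
    if not speeds:
        raise ParameterError("no usable snapshot pairs for wave speed")
    return float(np.mean(speeds) / math.sqrt(D * lambda_e))


def _amplitude_growth_rate(trajectory: Trajectory, fraction: float = 0.5) -> float | None:
    """Fitted exponential rate of the pattern amplitude over the late run.

    Least-squares slope of log(amplitude) versus time on the last
    ``fraction`` of the monitor series; None when the monitor is too short
    or the amplitude hits zero.
    """
    mon = trajectory.monitor
    if not mon or mon["t"].size < 10:
        return None
    t = mon["t"]
    amp = mon["amplitude"]
    i0 = int(t.size * (1.0 - fraction))
    t, amp = t[i0:], amp[i0:]
    if np.any(amp <= 0):
        return None
    coeff = np.polyfit(t, np.log(amp), 1)
    return float(coeff[0])


def classify_pattern(
    trajectory: Trajectory,
    amplitude_threshold: float = 1e-2,
    speed_tol: float = 1e-2,
    rate_fallback: bool = True,
) -> PatternVerdict:
    """Classify a long-time solution as uniform, static wave or traveling wave.

    The relative amplitude of the final snapshot decides when it is
    conclusive: below threshold on a converged (or amplitude-decayed) run
    is uniform, above threshold is a wave whose measured dimensionless
    speed separates static (|v_s| < speed_tol) from traveling.  An
    unconverged run that ends below threshold is decided by the sign of the
    late-time amplitude growth rate when ``rate_fallback`` is enabled
    (marked inconclusive otherwise).
    """
    final = FieldState(rho=trajectory.states[-1], t=float(trajectory.times[-1]))
    amp = final.amplitude()
    rate = _amplitude_growth_rate(trajectory)
    if amp < 1e-3 * amplitude_threshold:
        # at the numerical noise floor: nothing is growing here
        return PatternVerdict(kind="uniform", amplitude=amp, growth_rate=rate)
    if amp >= amplitude_threshold:
        vs = wave_speed(trajectory)
        kind = "static_wave" if abs(vs) < speed_tol else "traveling_wave"
        return PatternVerdict(kind=kind, amplitude=amp, v_s=vs, growth_rate=rate)
    settled = trajectory.converged or trajectory.stop_reason == "amp_low"
    if settled:
        return PatternVerdict(kind="uniform", amplitude=amp, growth_rate=rate)
    if rate_fallback and rate is not None:
        if rate > 0.0:
            # growing towards a wave; speed not yet measurable reliably
            vs = None
            try:
                vs = wave_speed(trajectory)
            except ParameterError:
                pass
            kind = "traveling_wave"
            if vs is not None and abs(vs) < speed_tol:
                kind = "static_wave"
            return PatternVerdict(kind=kind, amplitude=amp, v_s=vs,
                                  growth_rate=rate, conclusive=False)
        return PatternVerdict(kind="uniform", amplitude=amp, growth_rate=rate,
                              conclusive=False)
    return PatternVerdict(kind="inconclusive", amplitude=amp, growth_rate=rate,
                          conclusive=False)


@dataclass
class StateDiagram:
    """Wave/no-wave scan over the (v_r, v_m) plane with its separatrix fit."""

    v_r: np.ndarray
    v_m_transition: np.ndarray
    fit: SeparatrixFit
    cells: list  # (v_r, v_m, PatternVerdict) for every run performed


def _run_cell(
    v_r: float,
    v_m: float,
    params: ModelParams,
    grid: Grid,
    config: SolverConfig,
    R0: float,
    amplitude_threshold: float,
) -> PatternVerdict:
    vp, vmn = speeds_from_vm_vr(v_m, v_r, params.transport.D, params.rates.lambda_e)
    p = params.with_(transport=Transport(vp, vmn, params.transport.D))
    init = add_gaussian_noise(
        init_uniform_stationary(p, grid, R0=R0), config.noise_amplitude, config.seed
    )
    cfg = replace(config, stop_amp_high=5.0 * amplitude_threshold, shape_tol=None)
    traj = integrate(init, p, grid, cfg)
    return classify_pattern(traj, amplitude_threshold=amplitude_threshold)


def state_diagram(
    v_r_grid,
    params: ModelParams,
    grid: Grid | None = None,
    config: SolverConfig | None = None,
    v_m_bracket: tuple[float, float] = (1.0, 6.0),
    bisect_depth: int = 6,
    R0: float = 1.0,
    amplitude_threshold: float = 1e-2,
) -> StateDiagram:
    """Numerical wave/no-wave state diagram with quadratic separatrix fit.

    For each v_r the transition v_m is located by bisection on the verdict
    of full PDE runs (wave below, uniform above — faster running smears the
    attraction-driven instability out) and the transition points are fitted
    with a quadratic.  The initial condition of every run is the uniform
    stationary state with conserved density R0 plus seeded Gaussian noise.
    """
    grid = grid or Grid(1.0, 128)
    config = config or SolverConfig(dt=1e-4, n_steps=200_000, snapshot_stride=20_000)
    v_r_grid = np.atleast_1d(np.asarray(v_r_grid, dtype=float))
    cells = []
    transitions = np.empty_like(v_r_grid)

    def is_wave(v_r: float, v_m: float) -> bool:
        verdict = _run_cell(v_r, v_m, params, grid, config, R0, amplitude_threshold)
        cells.append((float(v_r), float(v_m), verdict))
        return verdict.kind in ("static_wave", "traveling_wave")

    for j, v_r in enumerate(v_r_grid):
        a, b = v_m_bracket
        if not is_wave(v_r, a):
            raise ParameterError(f"no wave at v_m={a:g}, v_r={v_r:g}: bracket too high")
        if is_wave(v_r, b):
            raise ParameterError(f"wave persists at v_m={b:g}, v_r={v_r:g}: bracket too low")
        for _ in range(bisect_depth):
            mid = 0.5 * (a + b)
            if is_wave(v_r, mid):
                a = mid
            else:
                b = mid
        transitions[j] = 0.5 * (a + b)
    fit = quadratic_fit(v_r_grid, transitions)
    return StateDiagram(v_r=v_r_grid, v_m_transition=transitions, fit=fit, cells=cells)
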