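"""Reproducible field-state fixtures for tests and validation.

Every fixture is generated from an explicit seed, so the same call yields
bit-identical arrays (and files).  The ``translated_wave`` kind builds a
synthetic trajectory whose profile is rigidly translated at an imposed
speed using exact spectral shifts — the ground truth against which the
cross-correlation wave-speed estimator is validated.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, ParameterError
from .pde import FieldState, Grid, SolverConfig, Trajectory, add_gaussian_noise, init_gaussian_peak, init_uniform_stationary

__all__ = ["generate_fixture", "make_translated_trajectory", "save_fixture"]


def _spectral_translate(field: np.ndarray, shift: float, L: float) -> np.ndarray:
    """Translate a periodic field by an arbitrary (sub-grid) shift."""
    n = field.shape[-1]
    k = 2.0 * np.pi * np.fft.rfftfreq(n, d=L / n)
    return np.fft.irfft(np.fft.rfft(field) * np.exp(-1j * k * shift), n=n)


def make_translated_trajectory(
    grid: Grid,
    params: ModelParams,
    speed: float,
    dt_snap: float = 1.0,
    n_snap: int = 8,
    seed: int = 0,
) -> Trajectory:
    """Synthetic trajectory: a fixed random smooth profile moving at ``speed``.

    The profile is a positive band-limited random field (a few low Fourier
    modes on top of a uniform background), identical for all three species
    up to amplitude, translated rigidly between snapshots.  Labelled
    synthetic: it is *not* a PDE solution.
    """
    rng = np.random.default_rng(seed)
    x = grid.x
    base = np.ones(grid.n_x)
    for mode in range(1, 4):
        amp = rng.uniform(0.1, 0.3) / mode
        phase = rng.uniform(0, 2 * np.pi)
        base += amp * np.cos(2 * np.pi * mode * x / grid.L + phase)
    profile = np.vstack([0.5 * base, base, 0.5 * base])
    times = np.arange(n_snap) * dt_snap
    states = np.empty((n_snap, 3, grid.n_x))
    for i, t in enumerate(times):
        shift = speed * t
        for s in range(3):
            states[i, s] = _spectral_translate(profile[s], shift, grid.L)
    return Trajectory(
        times=times,
        states=states,
        grid=grid,
        params=params,
        config=SolverConfig(dt=dt_snap, n_steps=0, snapshot_stride=1),
        converged=True,
        stop_reason="synthetic",
    )


def generate_fixture(
    kind: str,
    seed: int = 0,
    params: ModelParams | None = None,
    grid: Grid | None = None,
    **kwargs,
):
    """Build one of the named fixtures: uniform | noisy | peak | translated_wave.

    ``uniform``/``noisy`` need ``params`` (stationary state, optionally plus
    Gaussian noise of amplitude kwargs['amplitude']); ``peak`` builds a
    narrow settled-cell Gaussian; ``translated_wave`` a rigidly moving
    synthetic trajectory with imposed kwargs['speed'].
    """
    grid = grid or Grid(1.0, 128)
    if kind in ("uniform", "noisy"):
        if params is None:
            raise ParameterError(f"fixture {kind!r} requires model parameters")
        state = init_uniform_stationary(params, grid, R0=kwargs.get("R0", 1.0))
        if kind == "noisy":
            state = add_gaussian_noise(state, kwargs.get("amplitude", 1e-3), seed)
        return state
    if kind == "peak":
        return init_gaussian_peak(grid, width=kwargs.get("width", 3 * grid.dx),
                                  mass=kwargs.get("mass", 1.0))
    if kind == "translated_wave":
        if params is None:
            raise ParameterError("fixture 'translated_wave' requires model parameters")
        return make_translated_trajectory(
            grid, params, speed=kwargs.get("speed", 0.03),
            dt_snap=kwargs.get("dt_snap", 1.0), n_snap=kwargs.get("n_snap", 8),
            seed=seed,
        )
    raise ParameterError(f"unknown fixture kind {kind!r}")


def save_fixture(obj, path) -> None:
    """Write a fixture deterministically (FieldState or Trajectory) as npz."""
    if isinstance(obj, Trajectory):
        obj.save_npz(path)
    elif isinstance(obj, FieldState):
        np.savez(path, rho=obj.rho, t=obj.t)
    else:
        raise TypeError(f"cannot save object of type {type(obj)!r}")
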