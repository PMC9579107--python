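"""Fourier-space solution of the free spatial model: ISF and displacement moments.

For non-interacting cells the spatial model is linear and diagonal in
wavenumber k: rho~(k,t) = exp[(-k^2 Dmat - i k Vmat + M) t] rho~(k,0).
The intermediate scattering function (ISF) built from this solution
generates the displacement moments by k-differentiation at k = 0,

    <(x - x0)^n> = i^n / N(t) * d^n F(k,t)/dk^n | k=0,

with per-population analogues normalized by N_alpha.  Rather than
finite-differencing in k, the k-derivatives are obtained exactly: the vectors
y_m = d^m rho~/dk^m at k = 0 satisfy a closed block-triangular linear ODE
(obtained by differentiating the Fourier evolution equation m times), which
is solved with one matrix exponential.  A central finite-difference fallback
in k with Richardson extrapolation is provided for cross-checking.

The default initial condition is a single settled cell at the origin,
rho(x,0) = (0, delta(x), 0), i.e. rho~(k,0) = (0, 1, 0) — the paperless way
of saying "one cell in the act of dividing".  Its hallmark is a
super-ballistic t^3 regime of the settled-population MD and MSD at early
times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb

import numpy as np
import scipy.linalg

from .params import (
    DensityTriple,
    ModelParams,
    ParameterError,
    UnsupportedRegimeError,
    derived_speeds,
)
from .wellmixed import eigenvalues

__all__ = [
    "DELTA_INIT",
    "SpectralPropagator",
    "MomentSeries",
    "CrossoverTimes",
    "propagator",
    "isf",
    "moment",
    "moment_fd",
    "short_time_coefficients",
    "crossing_times",
    "long_time_md_slope",
    "long_time_msd_crossover",
]

#: Fourier transform of the settled-delta initial condition (0, delta(x), 0)
DELTA_INIT = np.array([0.0, 1.0, 0.0], dtype=complex)

_SELECTORS = {"total": None, "plus": 0, "settled": 1, "minus": 2}


def _require_free(params: ModelParams) -> None:
    if not params.interactions.free:
        raise UnsupportedRegimeError(
            "the Fourier-space solution holds for free cells only (kappa = kappa_0 = 0)"
        )


def _spectral_matrix(k: float, params: ModelParams) -> np.ndarray:
    """A(k) = -k^2 Dmat - i k Vmat + M, the generator of rho~(k, t)."""
    return (-(k * k)) * params.diffusion_matrix - 1j * k * params.velocity_matrix + params.M.astype(complex)


@dataclass(frozen=True)
class SpectralPropagator:
    """exp[A(k) t]; at k = 0 it reduces to the well-mixed propagator exp(M t)."""

    k: float
    t: float
    matrix: np.ndarray


def propagator(k: float, t: float, params: ModelParams) -> SpectralPropagator:
    """Exact Fourier-space propagator of the free model at wavenumber k, time t."""
    _require_free(params)
    if t < 0.0:
        raise ParameterError("t must be >= 0")
    mat = scipy.linalg.expm(_spectral_matrix(k, params) * t)
    return SpectralPropagator(k=float(k), t=float(t), matrix=mat)


def isf(
    k: float,
    t: float,
    params: ModelParams,
    init: np.ndarray | None = None,
    selector: str = "total",
) -> complex:
    """Intermediate scattering function F(k, t).

    ``init`` is the Fourier transform of the initial densities at wavenumber
    k (defaults to the settled-delta condition (0, 1, 0), which is
    k-independent).  For the total population

        F(k,t) = P~(k,t) P~(-k,0) N(t) = S(k,t) S(-k,0) / N(0)

    with S = sum_alpha rho~_alpha, so F(0,t) = N(t).  Per population,
    F_alpha = rho~_alpha(k,t) rho~_alpha(-k,0) / N_alpha(0).
    """
    _require_free(params)
    if selector not in _SELECTORS:
        raise ValueError(f"selector must be one of {sorted(_SELECTORS)}")
    y0 = DELTA_INIT if init is None else np.asarray(init, dtype=complex)
    # conjugate-wavenumber initial transform; for a real initial density
    # rho~(-k, 0) = conj(rho~(k, 0))
    y0_neg = np.conj(y0)
    rho_kt = propagator(k, t, params).matrix @ y0
    # particle numbers from the k=0 transform of the same initial condition
    n0_vec = propagator(0.0, 0.0, params).matrix @ y0  # = y0, kept for clarity
    if selector == "total":
        N0 = complex(np.sum(n0_vec))
        if N0 == 0:
            raise ParameterError("ISF undefined: N(0) = 0")
        return complex(np.sum(rho_kt) * np.sum(y0_neg) / N0)
    idx = _SELECTORS[selector]
    Na0 = complex(n0_vec[idx])
    if Na0 == 0:
        raise ParameterError(f"ISF undefined: N_{selector}(0) = 0")
    return complex(rho_kt[idx] * y0_neg[idx] / Na0)


@dataclass(frozen=True)
class MomentSeries:
    """Time series of <(x - x0)^n> for a chosen population."""

    selector: str
    order: int
    times: np.ndarray
    values: np.ndarray


def _derivative_stack(params: ModelParams, n: int, times: np.ndarray,
                      init_derivs: np.ndarray) -> np.ndarray:
    """y_m(t) = d^m rho~/dk^m at k=0 for m = 0..n, shape (nt, n+1, 3).

    Differentiating d rho~/dt = A(k) rho~ m times at k = 0 (A is quadratic
    in k) gives the closed block system

        dy_m/dt = M y_m - i m V y_{m-1} - m (m-1) Dmat y_{m-2},

    solved exactly with a single (3(n+1))-dimensional matrix exponential.
    """
    Dmat = params.diffusion_matrix.astype(complex)
    V = params.velocity_matrix.astype(complex)
    M = params.M.astype(complex)
    dim = 3 * (n + 1)
    B = np.zeros((dim, dim), dtype=complex)
    for m in range(n + 1):
        B[3 * m : 3 * m + 3, 3 * m : 3 * m + 3] = M
        if m >= 1:
            B[3 * m : 3 * m + 3, 3 * (m - 1) : 3 * (m - 1) + 3] = -1j * m * V
        if m >= 2:
            B[3 * m : 3 * m + 3, 3 * (m - 2) : 3 * (m - 2) + 3] = -m * (m - 1) * Dmat
    y_init = init_derivs.reshape(dim)
    out = np.empty((times.size, n + 1, 3), dtype=complex)
    for i, t in enumerate(times):
        z = scipy.linalg.expm(B * t) @ y_init
        out[i] = z.reshape(n + 1, 3)
    return out


def _init_derivs(n: int, init: np.ndarray | None) -> np.ndarray:
    """k-derivatives at k=0 of the initial transform; rows m = 0..n.

    The default settled-delta initial condition has rho~(k,0) = (0,1,0)
    independent of k, so all derivatives beyond order 0 vanish.  A custom
    (n+1, 3) array may be supplied for other initial conditions.
    """
    if init is None:
        d = np.zeros((n + 1, 3), dtype=complex)
        d[0] = DELTA_INIT
        return d
    init = np.asarray(init, dtype=complex)
    if init.shape == (3,):
        d = np.zeros((n + 1, 3), dtype=complex)
        d[0] = init
        return d
    if init.shape != (n + 1, 3):
        raise ValueError(f"init must have shape (3,) or ({n + 1}, 3), got {init.shape}")
    return init.copy()


def moment(
    n: int,
    times,
    params: ModelParams,
    init: np.ndarray | None = None,
    selector: str = "total",
) -> MomentSeries:
    """n-th displacement moment <(x - x0)^n> versus time (exact, no k-stepping).

    ``selector`` chooses the weighting density: ``total`` uses
    P = (rho_+ + rho_0 + rho_-)/N, the per-population selectors use
    rho_alpha / N_alpha.  ``init`` optionally supplies the k-derivatives of
    the initial transform (see :func:`_init_derivs`); the default is the
    settled-delta condition, for which x0 = 0.
    """
    _require_free(params)
    if n < 1:
        raise ParameterError("moment order n must be >= 1")
    if selector not in _SELECTORS:
        raise ValueError(f"selector must be one of {sorted(_SELECTORS)}")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    d0 = _init_derivs(n, init)
    ys = _derivative_stack(params, n, times, d0)
    vals = np.empty(times.size)
    if selector == "total":
        # F(k,t) = S(k,t) * S0(-k) / N(0);  d^j_k S0(-k)|_0 = (-1)^j sum_a d0[j,a]
        S0_derivs = np.array([(-1.0) ** j * np.sum(d0[j]) for j in range(n + 1)])
        N0 = S0_derivs[0].real
        if N0 == 0:
            raise ParameterError("moment undefined: N(0) = 0")
        for i in range(times.size):
            S_derivs = ys[i].sum(axis=1)  # d^m_k S(k,t)|_0
            Nt = S_derivs[0].real
            dF = sum(comb(n, m) * S_derivs[m] * S0_derivs[n - m] for m in range(n + 1)) / N0
            vals[i] = ((1j) ** n * dF / Nt).real
    else:
        a = _SELECTORS[selector]
        Na0 = d0[0, a].real
        if Na0 == 0:
            raise ParameterError(f"moment undefined: N_{selector}(0) = 0")
        r0_derivs = np.array([(-1.0) ** j * d0[j, a] for j in range(n + 1)])
        for i in range(times.size):
            ra_derivs = ys[i][:, a]
            Nat = ra_derivs[0].real
            if Nat == 0:
                raise ParameterError(f"moment undefined: N_{selector}(t={times[i]:g}) = 0")
            dF = sum(comb(n, m) * ra_derivs[m] * r0_derivs[n - m] for m in range(n + 1)) / Na0
            vals[i] = ((1j) ** n * dF / Nat).real
    return MomentSeries(selector=selector, order=n, times=times, values=vals)


def moment_fd(
    n: int,
    t: float,
    params: ModelParams,
    init: np.ndarray | None = None,
    selector: str = "total",
    h: float = 1e-3,
) -> float:
    """Finite-difference cross-check of :func:`moment` (central stencil in k,
    one Richardson extrapolation step).  Supports k-independent initial
    transforms only; slower and less accurate than the exact derivative path,
    which it is used to validate in tests."""
    base = DELTA_INIT if init is None else np.asarray(init, dtype=complex)
    if base.shape != (3,):
        raise ValueError("moment_fd supports a k-independent initial transform of shape (3,)")

    def dF(h_: float) -> complex:
        # weights of the (2n+1)-point central stencil for the n-th derivative
        w = np.array([1.0])
        for _ in range(n):
            w = np.convolve(w, [0.5, 0.0, -0.5])
        offsets = np.arange(n, -n - 1, -1)  # convolve output runs from +n to -n
        tot = 0.0 + 0.0j
        for off, w_ in zip(offsets, w):
            if w_ != 0.0:
                tot += w_ * isf(off * h_, t, params, init=base, selector=selector)
        return tot / h_**n

    a1, a2 = dF(h), dF(h / 2.0)
    dFn = (4.0 * a2 - a1) / 3.0  # Richardson, error ~ h^2 for central stencils
    # F(0,t) = N(t) and F_alpha(0,t) = N_alpha(t): the k=0 ISF is the normalization
    Nt = isf(0.0, t, params, init=base, selector=selector).real
    return ((1j) ** n * dFn / Nt).real


def short_time_coefficients(params: ModelParams, selector: str = "total") -> dict:
    """Leading two short-time expansion coefficients of MD and MSD.

    For the settled-delta initial condition the expansions are

    total population:
        MD  = lambda_d v_d t^2 - (1/3) lambda_d v_d (2mu + 4lambda_d + lambda_s) t^3
        MSD = 2 D lambda_d t^2 - (2/3) lambda_d [D (2mu + 4lambda_d + lambda_s) - v_a^2] t^3
    settled population:
        MD  = (1/3) lambda_s lambda_d v_d t^3 - (1/6) lambda_s lambda_d v_d (mu - lambda_d + lambda_s) t^4
        MSD = (2/3) D lambda_s lambda_d t^3 - (1/6) lambda_s lambda_d [2D (mu - lambda_d + lambda_s) - v_a^2] t^4

    Returned as {"md": (c_lead, c_next), "msd": (...), "md_powers": (p, p+1),
    "msd_powers": (p, p+1)} with p = 2 (total) or 3 (settled).  The settled
    MSD with D = 0 has a vanishing t^3 coefficient — growth then starts at
    t^4, one order later.
    """
    r, tr = params.rates, params.transport
    ds = derived_speeds(tr, r.lambda_e) if tr.D > 0 and (tr.v_plus + tr.v_minus) > 0 else None
    v_d = (tr.v_plus - tr.v_minus) / 2.0
    v_a2 = (tr.v_plus**2 + tr.v_minus**2) / 2.0
    ls, ld, mu, D = r.lambda_s, r.lambda_d, r.mu, tr.D
    if selector == "total":
        return {
            "md": (ld * v_d, -(1.0 / 3.0) * ld * v_d * (2 * mu + 4 * ld + ls)),
            "msd": (2.0 * D * ld, -(2.0 / 3.0) * ld * (D * (2 * mu + 4 * ld + ls) - v_a2)),
            "md_powers": (2, 3),
            "msd_powers": (2, 3),
        }
    if selector == "settled":
        return {
            "md": ((1.0 / 3.0) * ls * ld * v_d, -(1.0 / 6.0) * ls * ld * v_d * (mu - ld + ls)),
            "msd": ((2.0 / 3.0) * D * ls * ld, -(1.0 / 6.0) * ls * ld * (2 * D * (mu - ld + ls) - v_a2)),
            "md_powers": (3, 4),
            "msd_powers": (3, 4),
        }
    raise UnsupportedRegimeError(
        "short-time expansions are available for the 'total' and 'settled' selectors "
        "with the settled-delta initial condition only"
    )


@dataclass(frozen=True)
class CrossoverTimes:
    """Crossover times between successive power-law regimes of MD / MSD.

    Each is the ratio of the absolute values of two consecutive expansion
    coefficients; an exactly cancelling denominator yields +inf.  t_l2 — the
    long-time diffusive-to-ballistic crossover of the MSD — has no compact
    closed form and is computed numerically on request
    (:func:`long_time_msd_crossover`).
    """

    t_c1: float
    t_c2: float
    t_c0_1: float
    t_c0_2: float
    t_l2: float | None = None


def _safe_ratio(num: float, den: float) -> float:
    return math.inf if den == 0.0 else num / abs(den)


def crossing_times(params: ModelParams, compute_t_l2: bool = False) -> CrossoverTimes:
    """Closed-form crossover times of the short-time MD/MSD regimes.

    t_c1   total MD,   t^2 -> t^3:  3 / (2mu + 4lambda_d + lambda_s)
    t_c2   total MSD,  t^2 -> t^3:  3D / |D (2mu + 4lambda_d + lambda_s) - v_a^2|
    t_c0_1 settled MD, t^3 -> t^4:  2 / |mu - lambda_d + lambda_s|
    t_c0_2 settled MSD,t^3 -> t^4:  4D / |2D (mu - lambda_d + lambda_s) - v_a^2|
    """
    r, tr = params.rates, params.transport
    ls, ld, mu, D = r.lambda_s, r.lambda_d, r.mu, tr.D
    v_a2 = (tr.v_plus**2 + tr.v_minus**2) / 2.0
    t_c1 = _safe_ratio(3.0, 2 * mu + 4 * ld + ls)
    t_c2 = _safe_ratio(3.0 * D, D * (2 * mu + 4 * ld + ls) - v_a2)
    t_c0_1 = _safe_ratio(2.0, mu - ld + ls)
    t_c0_2 = _safe_ratio(4.0 * D, 2 * D * (mu - ld + ls) - v_a2)
    t_l2 = long_time_msd_crossover(params) if compute_t_l2 else None
    return CrossoverTimes(t_c1=t_c1, t_c2=t_c2, t_c0_1=t_c0_1, t_c0_2=t_c0_2, t_l2=t_l2)


def long_time_md_slope(params: ModelParams) -> float:
    """Asymptotic linear-in-t slope of the total mean displacement,

        MD ~ 4 v_d lambda_d lambda_s / [Lambda (mu - lambda_d + lambda_s + Lambda)] * t.

    Zero for equal speeds (the MD then saturates).
    """
    r, tr = params.rates, params.transport
    v_d = (tr.v_plus - tr.v_minus) / 2.0
    if v_d == 0.0:
        return 0.0
    Lam = eigenvalues(r).Lambda
    if isinstance(Lam, complex):
        raise UnsupportedRegimeError("long-time MD slope undefined for complex eigenvalues")
    denom = Lam * (r.mu - r.lambda_d + r.lambda_s + Lam)
    if denom == 0.0:
        raise ParameterError("long-time MD slope undefined: vanishing denominator")
    return 4.0 * v_d * r.lambda_d * r.lambda_s / denom


def long_time_msd_crossover(
    params: ModelParams,
    t_window: tuple[float, float] = (1e2, 1e6),
    n_points: int = 60,
) -> float:
    """Numerical surrogate for the diffusive-to-ballistic MSD crossover t_l2.

    The closed form is unwieldy; operationally t_l2 is the intersection of
    the fitted long-time diffusive asymptote (a + 2 D_eff t) with the
    ballistic asymptote (slope^2 t^2, slope from :func:`long_time_md_slope`),
    with the diffusive line fitted by least squares on log-spaced samples of
    the exact MSD restricted to the window where the local log-log slope is
    close to 1.  Requires v_plus != v_minus (otherwise no ballistic regime).
    """
    c = long_time_md_slope(params)
    if c == 0.0:
        raise UnsupportedRegimeError("no ballistic regime for equal speeds: t_l2 undefined")
    ts = np.geomspace(t_window[0], t_window[1], n_points)
    msd = moment(2, ts, params).values
    logs = np.gradient(np.log(msd), np.log(ts))
    diffusive = np.abs(logs - 1.0) < 0.2
    if diffusive.sum() < 5:
        # window missed the diffusive regime; fall back to the early part
        diffusive = np.zeros_like(diffusive, dtype=bool)
        diffusive[: max(5, n_points // 6)] = True
    A = np.vstack([np.ones(diffusive.sum()), ts[diffusive]]).T
    a, b = np.linalg.lstsq(A, msd[diffusive], rcond=None)[0]
    # intersection a + b t = c^2 t^2  ->  positive root
    disc = b * b + 4.0 * c * c * a
    root = (b + math.sqrt(max(disc, 0.0))) / (2.0 * c * c)
    if root <= 0.0:
        raise ParameterError("t_l2 fit failed: non-positive intersection")
    return float(root)
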