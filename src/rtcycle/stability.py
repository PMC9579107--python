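"""Linear stability of the homogeneous state with attraction and repulsion.

Linearizing the interacting model about the symmetric homogeneous stationary
state (rho^_+, rho^_0, rho^_-) and Fourier transforming in space yields a
3x3 wavenumber-dependent Jacobian J(k) whose eigenvalues s_i(k) are the
growth rates of plane-wave perturbations.  The branch s_1 of largest real
part controls pattern formation:

* s_1(0) = E3, the unstable kinetic eigenvalue;
* without settled-cell repulsion (kappa_0 = 0) the short-wave limit is
  s_1(inf) = 2 kappa rho^_+ lambda_s / D - lambda_d, giving the two endpoint
  stability conditions mu >= lambda_s and lambda_d >= 2 kappa rho^_+ lambda_s / D;
* with kappa_0 > 0 the short-wave behavior is -kappa_0 rho^_0 k^2, so the
  unstable band is bounded and its largest root k_r sets the smallest
  unstable length l = 2 pi / k_r.  Patterns require k_r > k0 = 2 pi / L.

The separatrix k_r = k0 in the (v_r, v_m) plane of reduced speed difference
and dimensionless maximum speed is located by bisection and summarized by a
least-squares quadratic v_m^f(v_r) = c0 + c1 v_r + c2 v_r^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import (
    ModelParams,
    ParameterError,
    speeds_from_vm_vr,
    Transport,
)
from .wellmixed import eigenvalues

__all__ = [
    "HomogeneousState",
    "DispersionBranch",
    "SeparatrixFit",
    "fourier_jacobian",
    "dispersion_branches",
    "s1_limits",
    "is_stable",
    "largest_unstable_root",
    "separatrix_fit",
    "quadratic_fit",
]


@dataclass(frozen=True)
class HomogeneousState:
    """Symmetric homogeneous stationary state used as the linearization point.

    The mover densities are equal (rho^_+ = rho^_-) and the settled density
    follows the stationary ratio rho^_0 / rho^_+ = 2 mu / lambda_d.
    """

    rho_hat_plus: float
    rho_hat_0: float
    rho_hat_minus: float

    @classmethod
    def from_params(cls, params: ModelParams, rho_hat_plus: float = 1.0) -> "HomogeneousState":
        """Build the state from the stationary ratios, normalizing rho^_+.

        The absolute density scale drops out of the linear model only through
        the products kappa*rho^ and kappa_0*rho^; rho^_+ = 1 is the
        package default normalization in dimensionless units.
        """
        r = params.rates
        if r.lambda_d <= 0:
            raise ParameterError("homogeneous state requires lambda_d > 0")
        return cls(
            rho_hat_plus=rho_hat_plus,
            rho_hat_0=2.0 * r.mu / r.lambda_d * rho_hat_plus,
            rho_hat_minus=rho_hat_plus,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_hat_plus, self.rho_hat_0, self.rho_hat_minus])


def fourier_jacobian(k: float, params: ModelParams, hs: HomogeneousState) -> np.ndarray:
    """J(k) with d/dt delta-rho~ = J(k) delta-rho~; J(0) equals the kinetic matrix M.

    Transport enters the mover rows as -i k v_+/- - D k^2 on the diagonal;
    the attraction couples movers to the settled perturbation with
    +kappa rho^_+/- k^2, and the settled row carries the repulsive
    self-term -kappa_0 rho^_0 k^2.
    """
    J = params.M.astype(complex)
    D = params.transport.D
    vp, vm = params.transport.v_plus, params.transport.v_minus
    kap, kap0 = params.interactions.kappa, params.interactions.kappa_0
    k2 = k * k
    J[0, 0] += -1j * k * vp - D * k2
    J[2, 2] += 1j * k * vm - D * k2
    J[0, 1] += kap * hs.rho_hat_plus * k2
    J[2, 1] += kap * hs.rho_hat_minus * k2
    J[1, 1] += -kap0 * hs.rho_hat_0 * k2
    return J


@dataclass(frozen=True)
class DispersionBranch:
    """Eigenvalue branches s_i(k) of J(k), continuity-tracked across k.

    ``s`` has shape (nk, 3); column 0 is the branch s_1 that starts at the
    kinetic eigenvalue E3 at k = 0 (the only branch that can go unstable).
    ``max_real`` is the pointwise largest real part over all branches,
    which is the physically relevant growth rate.
    """

    k: np.ndarray
    s: np.ndarray

    @property
    def s1(self) -> np.ndarray:
        return self.s[:, 0]

    @property
    def max_real(self) -> np.ndarray:
        return self.s.real.max(axis=1)


def _eigs_grid(kgrid: np.ndarray, params: ModelParams, hs: HomogeneousState) -> np.ndarray:
    """Eigenvalues of J(k) for every k, shape (nk, 3), unordered."""
    kgrid = np.asarray(kgrid, dtype=float)
    J = np.empty((kgrid.size, 3, 3), dtype=complex)
    for i, k in enumerate(kgrid):
        J[i] = fourier_jacobian(k, params, hs)
    return np.linalg.eigvals(J)


def dispersion_branches(kgrid, params: ModelParams, hs: HomogeneousState) -> DispersionBranch:
    """Continuity-tracked dispersion relation on a wavenumber grid.

    At the first grid point the branches are ordered by descending real part
    (so branch 0 connects to E3 when the grid starts at k = 0); across
    consecutive k the eigenvalues are matched by minimal-distance assignment
    to avoid sorting artifacts where branches cross.
    """
    kgrid = np.atleast_1d(np.asarray(kgrid, dtype=float))
    ev = _eigs_grid(kgrid, params, hs)
    out = np.empty_like(ev)
    order = np.argsort(-ev[0].real)
    out[0] = ev[0][order]
    for i in range(1, kgrid.size):
        prev, cur = out[i - 1], ev[i]
        # greedy minimal-distance assignment over the 6 permutations of 3 items
        best, best_cost = None, math.inf
        for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
            cost = sum(abs(cur[p] - prev[j]) for j, p in enumerate(perm))
            if cost < best_cost:
                best, best_cost = perm, cost
        out[i] = cur[list(best)]
    return DispersionBranch(k=kgrid, s=out)


def s1_limits(params: ModelParams, hs: HomogeneousState, k_check: float = 1e3) -> dict:
    """Long- and short-wave limits of the leading growth-rate branch.

    Returns a dict with ``s1_at_0`` (= E3), and either ``s1_at_inf``
    (kappa_0 = 0, finite limit 2 kappa rho^_+ lambda_s / D - lambda_d) or
    ``large_k_quadratic_coeff`` (kappa_0 > 0, s_1 ~ -kappa_0 rho^_0 k^2).
    For D = 0 with kappa_0 = 0 the growth rate increases linearly in k and
    ``unbounded`` is set (the system is then unstable at all short waves).
    """
    r = params.rates
    kap, kap0 = params.interactions.kappa, params.interactions.kappa_0
    D = params.transport.D
    E3 = eigenvalues(r).E3
    out: dict = {"s1_at_0": E3}
    if kap0 > 0.0:
        out["large_k_quadratic_coeff"] = -kap0 * hs.rho_hat_0
        out["description"] = "s1(k) ~ -kappa_0*rho_hat_0*k^2 for k -> inf"
    elif D > 0.0:
        out["s1_at_inf"] = 2.0 * kap * hs.rho_hat_plus * r.lambda_s / D - r.lambda_d
        out["description"] = "s1(inf) = 2*kappa*rho_hat_plus*lambda_s/D - lambda_d"
    else:
        out["unbounded"] = True
        out["description"] = "D = 0 and kappa_0 = 0: s1(k) grows ~ k, always unstable"
    return out


def is_stable(params: ModelParams, hs: HomogeneousState, mode: str = "endpoints") -> dict:
    """Stability verdict of the homogeneous state.

    ``endpoints`` checks the two necessary conditions read off the k -> 0
    and k -> inf limits: mu >= lambda_s and (for kappa_0 = 0)
    lambda_d >= 2 kappa rho^_+ lambda_s / D.  ``full_scan`` additionally
    scans Re s_1 over a dense log-spaced wavenumber grid, catching
    mid-band instabilities the endpoints miss (and conversely confirming
    stability in endpoint-marginal cases).
    """
    if mode not in ("endpoints", "full_scan"):
        raise ValueError("mode must be 'endpoints' or 'full_scan'")
    r = params.rates
    lims = s1_limits(params, hs)
    cond1 = r.mu >= r.lambda_s or abs(lims["s1_at_0"].real if isinstance(lims["s1_at_0"], complex) else lims["s1_at_0"]) < 1e-14
    failed = []
    if not cond1:
        failed.append("growth: mu < lambda_s (number of cells grows exponentially)")
    if "s1_at_inf" in lims and lims["s1_at_inf"] > 1e-14:
        failed.append("short-wave: lambda_d < 2*kappa*rho_hat_plus*lambda_s/D")
    if lims.get("unbounded"):
        failed.append("short-wave: D = 0 with kappa_0 = 0, unstable at all large k")
    verdict = {"stable": not failed, "failed_conditions": failed, "mode": mode}
    if mode == "full_scan":
        kgrid = np.concatenate([[0.0], np.geomspace(1e-3, 1e3, 600)])
        mr = dispersion_branches(kgrid, params, hs).max_real
        worst = float(mr[1:].max())  # exclude k = 0 (marginal E3=0 cases)
        verdict["max_re_s1"] = worst
        verdict["stable"] = bool(worst <= 1e-10) and not failed
    return verdict


def _max_re(k: float, params: ModelParams, hs: HomogeneousState) -> float:
    return float(np.linalg.eigvals(fourier_jacobian(k, params, hs)).real.max())


def largest_unstable_root(
    params: ModelParams,
    hs: HomogeneousState,
    k_max: float,
    n_grid: int = 2000,
) -> float | None:
    """Largest k in (0, k_max] with Re s_1(k) = 0, or None if never unstable.

    Requires kappa_0 > 0 so that Re s_1 < 0 is guaranteed at large k.  The
    root is bracketed by a sign change on a dense linear grid and refined by
    Brent's method to relative tolerance 1e-8; if Re s_1(k_max) > 0 the
    bracket is declared too small.
    """
    if params.interactions.kappa_0 <= 0.0:
        raise ParameterError("largest_unstable_root requires kappa_0 > 0")
    kgrid = np.linspace(k_max / n_grid, k_max, n_grid)
    mr = _eigs_grid(kgrid, params, hs).real.max(axis=1)
    if mr[-1] > 0.0:
        raise ParameterError(f"Re s1({k_max:g}) > 0: k_max too small to bracket k_r")
    pos = np.nonzero(mr > 0.0)[0]
    if pos.size == 0:
        return None
    i = pos[-1]  # last positive sample; root lies in (k[i], k[i+1])
    a, b = kgrid[i], kgrid[i + 1]
    root = brentq(_max_re, a, b, args=(params, hs), xtol=1e-12, rtol=1e-10)
    return float(root)


@dataclass(frozen=True)
class SeparatrixFit:
    """Quadratic fit v_m^f(v_r) = c0 + c1 v_r + c2 v_r^2 of a separatrix."""

    c0: float
    c1: float
    c2: float
    sigma: np.ndarray
    v_r: np.ndarray
    v_m: np.ndarray
    residual_rms: float


def quadratic_fit(v_r: np.ndarray, v_m: np.ndarray) -> SeparatrixFit:
    """Least-squares quadratic with parameter standard errors from the fit covariance."""
    v_r = np.asarray(v_r, dtype=float)
    v_m = np.asarray(v_m, dtype=float)
    if v_r.size > 3:
        coeffs, cov = np.polyfit(v_r, v_m, 2, cov=True)
        sig = np.sqrt(np.diag(cov))[::-1]  # reorder to (c0, c1, c2)
    else:
        # an exactly-determined fit has no residual-based error estimate
        coeffs = np.polyfit(v_r, v_m, 2)
        sig = np.full(3, np.nan)
    c2, c1, c0 = coeffs
    resid = v_m - np.polyval(coeffs, v_r)
    return SeparatrixFit(
        c0=float(c0), c1=float(c1), c2=float(c2),
        sigma=sig, v_r=v_r, v_m=v_m,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def separatrix_fit(
    v_r_grid,
    params: ModelParams,
    hs: HomogeneousState | None = None,
    L: float = 1.0,
    v_m_bracket: tuple[float, float] = (0.1, 20.0),
    v_m_tol: float = 1e-4,
    k_max: float | None = None,
) -> SeparatrixFit:
    """Locate and fit the theoretical separatrix k_r = k0 = 2 pi / L.

    For each reduced speed difference v_r the dimensionless maximum speed is
    bisected for the value v_m^f at which the largest unstable wavenumber
    k_r equals the smallest wavenumber k0 the finite periodic domain admits;
    below v_m^f the domain supports the instability (patterns), above it
    does not.  The resulting points are fitted with a quadratic.
    """
    if hs is None:
        hs = HomogeneousState.from_params(params)
    v_r_grid = np.atleast_1d(np.asarray(v_r_grid, dtype=float))
    D, le = params.transport.D, params.rates.lambda_e
    k0 = 2.0 * math.pi / L
    if k_max is None:
        k_max = 25.0 * k0

    def g(v_m: float, v_r: float) -> float:
        vp, vm_ = speeds_from_vm_vr(v_m, v_r, D, le)
        p = params.with_(transport=Transport(vp, vm_, D))
        k_r = largest_unstable_root(p, hs, k_max=k_max)
        return (-k0) if k_r is None else (k_r - k0)

    v_ms = np.empty_like(v_r_grid)
    for j, v_r in enumerate(v_r_grid):
        a, b = v_m_bracket
        ga, gb = g(a, v_r), g(b, v_r)
        if ga <= 0.0 or gb >= 0.0:
            raise ParameterError(
                f"v_m bracket {v_m_bracket} does not straddle the separatrix at v_r={v_r:g} "
                f"(g(a)={ga:g}, g(b)={gb:g})"
            )
        while b - a > v_m_tol:
            mid = 0.5 * (a + b)
            if g(mid, v_r) > 0.0:
                a = mid
            else:
                b = mid
        v_ms[j] = 0.5 * (a + b)
    return quadratic_fit(v_r_grid, v_ms)
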