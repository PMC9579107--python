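"""Space-independent population dynamics of the three-state model.

With interactions and transport switched off the densities obey the linear
kinetics d(rho)/dt = M rho, which is solved exactly by a matrix exponential.
The closed-form eigenvalues, the small-growth approximation of the unstable
eigenvalue, the stationary state on the separating line lambda_s = mu, and a
fixed-step RK4 integrator for the logistic (saturating) variant live here.
"""

from __future__ import annotations

import cmath
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .params import (
    CarryingCapacity,
    DensityTriple,
    KineticRates,
    ModelParams,
    ParameterError,
    build_rate_matrix,
    logistic_growth_vector,
    rate_matrix_split,
)

__all__ = [
    "EigenTriple",
    "eigenvalues",
    "unstable_eigenvalue_approx",
    "stationary_state",
    "evolve_linear",
    "evolve_nonlinear",
    "series_to_frame",
]

#: relative tolerance on |lambda_s - mu| for the stationary-state precondition
SEPARATRIX_RTOL = 1e-9


@dataclass(frozen=True)
class EigenTriple:
    """Closed-form eigenvalues of the kinetic matrix M.

    E1 = -(mu + 2*lambda_e + lambda_s) and E2 are always negative (stable);
    E3 carries the sign of lambda_s - mu and decides growth vs collapse of
    the colony.  Lambda is the discriminant
    sqrt((mu + lambda_d + lambda_s)^2 + 4*lambda_d*(lambda_s - mu)).
    """

    E1: float
    E2: complex
    E3: complex
    Lambda: complex

    def as_array(self) -> np.ndarray:
        return np.array([self.E1, self.E2, self.E3])


def eigenvalues(rates: KineticRates) -> EigenTriple:
    """Eigenvalues of the kinetic matrix in closed form.

    A negative radicand (never reached for the parameter regimes studied
    here, but possible) yields a complex-conjugate pair E2/E3, i.e. damped
    oscillations; a warning is emitted in that case.
    """
    ls, ld, le, mu = rates.lambda_s, rates.lambda_d, rates.lambda_e, rates.mu
    radicand = (mu + ld + ls) ** 2 + 4.0 * ld * (ls - mu)
    if radicand < 0.0:
        warnings.warn(
            "complex kinetic eigenvalues (damped oscillations): "
            f"discriminant radicand = {radicand:g} < 0",
            stacklevel=2,
        )
        Lam: complex = cmath.sqrt(complex(radicand))
    else:
        Lam = np.sqrt(radicand)
    E1 = -(mu + 2.0 * le + ls)
    E2 = -(mu + ld + ls + Lam) / 2.0
    E3 = -(mu + ld + ls - Lam) / 2.0
    if radicand >= 0.0:
        E2, E3, Lam = E2.real if hasattr(E2, "real") else E2, E3, Lam
        return EigenTriple(E1=float(E1), E2=float(np.real(E2)), E3=float(np.real(E3)), Lambda=float(np.real(Lam)))
    return EigenTriple(E1=float(E1), E2=E2, E3=E3, Lambda=Lam)


def unstable_eigenvalue_approx(rates: KineticRates) -> float:
    """Small-growth approximation E3 ~ lambda_d*(lambda_s - mu)/(mu + lambda_d + lambda_s).

    Valid when lambda_d*(lambda_s - mu) is small compared to
    (mu + lambda_d + lambda_s)^2.
    """
    denom = rates.mu + rates.lambda_d + rates.lambda_s
    if denom == 0.0:
        raise ParameterError("unstable_eigenvalue_approx undefined: mu + lambda_d + lambda_s = 0")
    return rates.lambda_d * (rates.lambda_s - rates.mu) / denom


def _check_separatrix(rates: KineticRates) -> None:
    scale = max(rates.lambda_s, rates.mu, rates.lambda_e)
    if abs(rates.lambda_s - rates.mu) > SEPARATRIX_RTOL * max(scale, 1e-300):
        raise ParameterError(
            "stationary state exists only on the separating line lambda_s = mu "
            f"(got lambda_s={rates.lambda_s}, mu={rates.mu})"
        )


def stationary_state(rates: KineticRates, R0: float) -> DensityTriple:
    """Stationary density triple on the line lambda_s = mu.

    R0 is the conserved combination rho_plus(0) + rho_minus(0) + 2*rho_0(0).
    The movers equilibrate symmetrically, rho_plus = rho_minus =
    lambda_d*R0/(2*(2*mu + lambda_d)), and rho_0 = mu*R0/(2*mu + lambda_d);
    for lambda_d = 2*mu all three populations coincide.
    """
    _check_separatrix(rates)
    if R0 < 0.0:
        raise ParameterError(f"R0 must be >= 0, got {R0}")
    mu, ld = rates.mu, rates.lambda_d
    denom = 2.0 * mu + ld
    if denom == 0.0:
        return DensityTriple(0.0, 0.0, 0.0) if R0 == 0.0 else DensityTriple(R0 / 2.0, 0.0, R0 / 2.0)
    mover = ld * R0 / (2.0 * denom)
    return DensityTriple(mover, mu * R0 / denom, mover)


def evolve_linear(init: DensityTriple, rates: KineticRates, times) -> np.ndarray:
    """Exact trajectory rho(t) = expm(M t) rho(0) of the linear kinetics.

    Uses scipy's scaling-and-squaring matrix exponential at each requested
    time (robust also at the defective point Lambda = 0 where M is not
    diagonalizable).  Returns an array of shape (len(times), 3).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0.0):
        raise ParameterError("times must be >= 0")
    M = build_rate_matrix(rates)
    rho0 = init.as_array()
    out = np.empty((times.size, 3))
    for i, t in enumerate(times):
        if t == 0.0:
            out[i] = rho0
        else:
            out[i] = scipy.linalg.expm(M * t) @ rho0
    return out


def evolve_nonlinear(
    init: DensityTriple,
    params: ModelParams,
    times,
    dt: float | None = None,
) -> np.ndarray:
    """Classical RK4 integration of d(rho)/dt = M_D rho + M_OD R(rho).

    R is the componentwise logistic source; the default step is
    1e-4/lambda_e.  Densities of a non-negative initial condition stay
    non-negative; a step producing values below -1e-9 aborts with
    diagnostics (signals a too-large dt).
    """
    if params.growth_mode != "logistic":
        raise ParameterError("evolve_nonlinear requires growth_mode='logistic'")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0.0) or np.any(np.diff(times) < 0.0):
        raise ParameterError("times must be >= 0 and non-decreasing")
    le = params.rates.lambda_e
    if dt is None:
        dt = 1e-4 / le if le > 0 else 1e-4
    M_D, M_OD = rate_matrix_split(params.rates)
    cap = params.carrying

    def rhs(rho: np.ndarray) -> np.ndarray:
        return M_D @ rho + M_OD @ logistic_growth_vector(rho, cap)

    rho = init.as_array().copy()
    t = 0.0
    out = np.empty((times.size, 3))
    for i, t_target in enumerate(times):
        while t < t_target - 1e-12 * max(t_target, 1.0):
            h = min(dt, t_target - t)
            k1 = rhs(rho)
            k2 = rhs(rho + 0.5 * h * k1)
            k3 = rhs(rho + 0.5 * h * k2)
            k4 = rhs(rho + h * k3)
            rho = rho + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
            if np.any(rho < -1e-9) or not np.all(np.isfinite(rho)):
                raise ParameterError(
                    f"nonlinear integration failed at t={t:g}: rho={rho} (reduce dt)"
                )
        out[i] = rho
    return out


def series_to_frame(times, series: np.ndarray) -> pd.DataFrame:
    """Tidy frame of a density trajectory: t, rho_plus, rho_0, rho_minus, N, R."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    series = np.asarray(series, dtype=float)
    df = pd.DataFrame(
        {
            "t": times,
            "rho_plus": series[:, 0],
            "rho_0": series[:, 1],
            "rho_minus": series[:, 2],
        }
    )
    df["N"] = df.rho_plus + df.rho_0 + df.rho_minus
    df["R"] = df.rho_plus + df.rho_minus + 2.0 * df.rho_0
    return df
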