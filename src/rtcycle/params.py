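"""Parameters and algebraic building blocks of the three-state run-and-tumble model.

The model describes a one-dimensional population of cells in three states:
right-movers (density ``rho_plus``), sedentary proliferating cells (``rho_0``)
and left-movers (``rho_minus``).  Movers settle at rate ``lambda_s``, reverse
direction at the tumble rate ``lambda_e`` and die at rate ``mu``; settled cells
double at rate ``lambda_d``, each division releasing one right- and one
left-moving daughter.  Movers self-propel at speeds ``v_plus`` / ``v_minus``
and diffuse with diffusivity ``D``; settled cells do not move.

Everything downstream (well-mixed kinetics, Fourier-space moments, linear
stability, the nonlinear PDE) is assembled from the objects defined here.

Units
-----
The package works in a nondimensional system: time in units of the inverse
tumble rate ``1/lambda_e``, length in units of the domain length ``L`` and
density dimensionless.  Presets are stored in these units; the *Caulobacter
crescentus* preset additionally carries SI values with explicit converters
(see :mod:`rtcycle.presets`).

Species ordering is ``(rho_plus, rho_0, rho_minus)`` everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SPECIES",
    "ParameterError",
    "UnsupportedRegimeError",
    "KineticRates",
    "Transport",
    "Interactions",
    "CarryingCapacity",
    "ModelParams",
    "DensityTriple",
    "DerivedSpeeds",
    "build_rate_matrix",
    "rate_matrix_split",
    "logistic_growth_vector",
    "derived_speeds",
]

#: canonical species ordering used for every vector/matrix in the package
SPECIES = ("rho_plus", "rho_0", "rho_minus")


class ParameterError(ValueError):
    """Raised when a model parameter violates its physical constraints."""


class UnsupportedRegimeError(ValueError):
    """Raised when an operation is asked outside its regime of validity."""


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ParameterError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class KineticRates:
    """Kinetic rates of the cell cycle, all in units of 1/time.

    ``lambda_s``: settling rate of movers; ``lambda_d``: doubling rate of
    settled cells; ``lambda_e``: tumble (direction-exchange) rate; ``mu``:
    death rate of movers (settled cells do not die in this model).
    """

    lambda_s: float
    lambda_d: float
    lambda_e: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("lambda_s", "lambda_d", "lambda_e", "mu"):
            object.__setattr__(self, name, _require_finite_nonneg(name, getattr(self, name)))


@dataclass(frozen=True)
class Transport:
    """Self-propulsion speeds of the two mover states and their diffusivity."""

    v_plus: float
    v_minus: float
    D: float

    def __post_init__(self) -> None:
        for name in ("v_plus", "v_minus", "D"):
            object.__setattr__(self, name, _require_finite_nonneg(name, getattr(self, name)))


@dataclass(frozen=True)
class Interactions:
    """Effective interaction strengths.

    ``kappa`` attracts movers towards regions of high settled density (biofilm
    seeding); ``kappa_0`` is the self-repulsion of settled cells (overcrowding
    avoidance).  Both act as density-dependent mobilities in the flux term
    d/dx[(d/dx U) rho] with U = diag(-kappa*rho_0, kappa_0*rho_0, -kappa*rho_0).
    """

    kappa: float = 0.0
    kappa_0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kappa", "kappa_0"):
            object.__setattr__(self, name, _require_finite_nonneg(name, getattr(self, name)))

    @property
    def free(self) -> bool:
        return self.kappa == 0.0 and self.kappa_0 == 0.0


@dataclass(frozen=True)
class CarryingCapacity:
    """Saturation densities of the logistic growth term; +inf = linear growth."""

    rho_plus_c: float = math.inf
    rho_0_c: float = math.inf
    rho_minus_c: float = math.inf

    def __post_init__(self) -> None:
        for name in ("rho_plus_c", "rho_0_c", "rho_minus_c"):
            value = float(getattr(self, name))
            if math.isnan(value) or value <= 0.0:
                raise ParameterError(f"{name} must be > 0 (possibly inf), got {value!r}")
            object.__setattr__(self, name, value)

    @classmethod
    def infinite(cls) -> "CarryingCapacity":
        return cls()

    @property
    def finite(self) -> bool:
        return all(math.isfinite(v) for v in self.as_array())

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_plus_c, self.rho_0_c, self.rho_minus_c], dtype=float)


@dataclass(frozen=True)
class DensityTriple:
    """The density vector rho = (rho_plus, rho_0, rho_minus)."""

    rho_plus: float
    rho_0: float
    rho_minus: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_plus, self.rho_0, self.rho_minus], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "DensityTriple":
        a = np.asarray(arr, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"expected shape (3,), got {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    @property
    def N(self) -> float:
        """Total cell number density."""
        return self.rho_plus + self.rho_0 + self.rho_minus

    @property
    def R(self) -> float:
        """The weighted population R = rho_plus + rho_minus + 2*rho_0.

        Counting settled cells twice makes R exactly conserved on the
        separating line lambda_s = mu of the linear kinetics.
        """
        return self.rho_plus + self.rho_minus + 2.0 * self.rho_0


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the model in one consistent unit system."""

    rates: KineticRates
    transport: Transport
    interactions: Interactions = field(default_factory=Interactions)
    carrying: CarryingCapacity = field(default_factory=CarryingCapacity)
    growth_mode: str = "linear"

    def __post_init__(self) -> None:
        if self.growth_mode not in ("linear", "logistic"):
            raise ParameterError(f"growth_mode must be 'linear' or 'logistic', got {self.growth_mode!r}")
        if self.growth_mode == "logistic" and not self.carrying.finite:
            raise ParameterError("growth_mode='logistic' requires a finite carrying capacity")
        if self.growth_mode == "linear" and self.carrying.finite:
            # linear growth <=> carrying treated as infinite; normalize silently
            object.__setattr__(self, "carrying", CarryingCapacity.infinite())

    # -- derived matrices -------------------------------------------------
    @property
    def M(self) -> np.ndarray:
        return build_rate_matrix(self.rates)

    @property
    def M_split(self) -> tuple[np.ndarray, np.ndarray]:
        return rate_matrix_split(self.rates)

    @property
    def diffusion_matrix(self) -> np.ndarray:
        """diag(D, 0, D): sedentary cells do not diffuse."""
        D = self.transport.D
        return np.diag([D, 0.0, D])

    @property
    def velocity_matrix(self) -> np.ndarray:
        """diag(v_plus, 0, -v_minus): signed advection speeds."""
        return np.diag([self.transport.v_plus, 0.0, -self.transport.v_minus])

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with selected top-level fields replaced."""
        return replace(self, **kwargs)


def build_rate_matrix(rates: KineticRates) -> np.ndarray:
    """Kinetic transition matrix M of the cell cycle, ordering (rho+, rho0, rho-).

    Column sums are (-mu, +lambda_d, -mu): the total cell number changes only
    through death of movers and doubling of settled cells.
    """
    ls, ld, le, mu = rates.lambda_s, rates.lambda_d, rates.lambda_e, rates.mu
    return np.array(
        [
            [-(ls + le + mu), ld, le],
            [ls, -ld, ls],
            [le, ld, -(ls + le + mu)],
        ],
        dtype=float,
    )


def rate_matrix_split(rates: KineticRates) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal (decay) and off-diagonal (growth) parts of M; M_D + M_OD == M."""
    M = build_rate_matrix(rates)
    M_D = np.diag(np.diag(M))
    return M_D, M - M_D


def logistic_growth_vector(state: DensityTriple | np.ndarray, carrying: CarryingCapacity) -> np.ndarray:
    """Componentwise logistic source rho_a * (1 - rho_a / rho_a,c).

    With an infinite carrying capacity this is the identity (linear growth).
    Negative densities pass through unchanged in sign; validation is the
    caller's concern.
    """
    rho = state.as_array() if isinstance(state, DensityTriple) else np.asarray(state, dtype=float)
    cap = carrying.as_array()
    with np.errstate(invalid="ignore"):
        out = rho * (1.0 - rho / cap)
    # inf capacity gives rho/cap == 0 exactly except at rho=+-inf, excluded by validation
    return out


@dataclass(frozen=True)
class DerivedSpeeds:
    """Derived speed scales used throughout the analysis.

    ``v_d``  half speed difference (v+ - v-)/2 — drives the mean displacement;
    ``v_a``  rms speed sqrt((v+^2 + v-^2)/2) — enters the MSD expansions;
    ``v_m``  dimensionless maximum speed max(v+, v-)/sqrt(D*lambda_e);
    ``v_r``  reduced speed difference (v+ - v-)/(v+ + v-), in [-1, 1].
    """

    v_d: float
    v_a: float
    v_m: float
    v_r: float


def derived_speeds(transport: Transport, lambda_e: float) -> DerivedSpeeds:
    """Compute the four derived speed scales from the bare transport parameters."""
    vp, vm_, D = transport.v_plus, transport.v_minus, transport.D
    if D <= 0.0:
        raise ParameterError("v_m requires D > 0")
    if lambda_e <= 0.0:
        raise ParameterError("v_m requires lambda_e > 0")
    if vp + vm_ <= 0.0:
        raise ParameterError("v_r requires v_plus + v_minus > 0")
    return DerivedSpeeds(
        v_d=(vp - vm_) / 2.0,
        v_a=math.sqrt((vp * vp + vm_ * vm_) / 2.0),
        v_m=max(vp, vm_) / math.sqrt(D * lambda_e),
        v_r=(vp - vm_) / (vp + vm_),
    )


def speeds_from_vm_vr(v_m: float, v_r: float, D: float, lambda_e: float) -> tuple[float, float]:
    """Invert (v_m, v_r) -> (v_plus, v_minus).

    v_m fixes the larger of the two speeds in units of sqrt(D*lambda_e) and
    v_r their normalized difference; for v_r >= 0 the larger speed is v_plus.
    """
    if not -1.0 <= v_r <= 1.0:
        raise ParameterError(f"v_r must lie in [-1, 1], got {v_r}")
    if v_m < 0.0:
        raise ParameterError(f"v_m must be >= 0, got {v_m}")
    vmax = v_m * math.sqrt(D * lambda_e)
    if v_r >= 0.0:
        v_plus = vmax
        v_minus = vmax * (1.0 - v_r) / (1.0 + v_r)
    else:
        v_minus = vmax
        v_plus = vmax * (1.0 + v_r) / (1.0 - v_r)
    return v_plus, v_minus
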