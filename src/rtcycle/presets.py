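"""Named parameter presets.

All presets are stored in the package's nondimensional unit system (time in
1/lambda_e, length in domain lengths L, density dimensionless).  The
*Caulobacter crescentus* preset is derived from experimentally measured SI
values (kept alongside) via :func:`dimensionless_from_si`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import (
    CarryingCapacity,
    DensityTriple,
    Interactions,
    KineticRates,
    ModelParams,
    Transport,
)

__all__ = ["Preset", "PRESETS", "get_preset", "dimensionless_from_si", "CC_TABLE_SI"]


@dataclass(frozen=True)
class Preset:
    """A named, ready-to-run parameter set with grid/solver defaults."""

    name: str
    params: ModelParams
    description: str
    L: float = 1.0
    n_x: int = 256
    dt: float = 1e-4
    n_steps: int = 1_000_000
    extras: dict = field(default_factory=dict)


#: measured SI parameters for Caulobacter crescentus (rates 1/s, speeds m/s, D m^2/s)
CC_TABLE_SI = {
    "lambda_e": 1e-1,
    "lambda_s": 1e-5,
    "lambda_d": 1e-4,
    "mu": 1e-6,
    "v_plus": 4e-5,
    "v_minus": 3.5e-5,
    "D": 2e-9,
}


def dimensionless_from_si(si: dict, L_si: float) -> dict:
    """Convert SI rates/speeds/diffusivity to the internal unit system.

    Time unit 1/lambda_e, length unit the physical domain length ``L_si``
    (meters): rates divide by lambda_e, speeds by lambda_e*L, D by
    lambda_e*L^2.
    """
    le = si["lambda_e"]
    if le <= 0 or L_si <= 0:
        raise ValueError("lambda_e and L_si must be positive")
    return {
        "lambda_e": 1.0,
        "lambda_s": si["lambda_s"] / le,
        "lambda_d": si["lambda_d"] / le,
        "mu": si["mu"] / le,
        "v_plus": si["v_plus"] / (le * L_si),
        "v_minus": si["v_minus"] / (le * L_si),
        "D": si["D"] / (le * L_si**2),
    }


def si_from_dimensionless(dimless: dict, lambda_e_si: float, L_si: float) -> dict:
    """Inverse of :func:`dimensionless_from_si`."""
    return {
        "lambda_e": lambda_e_si,
        "lambda_s": dimless["lambda_s"] * lambda_e_si,
        "lambda_d": dimless["lambda_d"] * lambda_e_si,
        "mu": dimless["mu"] * lambda_e_si,
        "v_plus": dimless["v_plus"] * lambda_e_si * L_si,
        "v_minus": dimless["v_minus"] * lambda_e_si * L_si,
        "D": dimless["D"] * lambda_e_si * L_si**2,
    }


#: physical domain length adopted for the Caulobacter preset (1 mm of channel)
CC_DOMAIN_SI = 1e-3

_cc_dimless = dimensionless_from_si(CC_TABLE_SI, CC_DOMAIN_SI)


def _mk(rates, transport, interactions=None, carrying=None, growth="linear"):
    return ModelParams(
        rates=KineticRates(*rates),
        transport=Transport(*transport),
        interactions=Interactions(*(interactions or (0.0, 0.0))),
        carrying=CarryingCapacity(*carrying) if carrying else CarryingCapacity.infinite(),
        growth_mode=growth,
    )


PRESETS: dict[str, Preset] = {}


def _register(p: Preset) -> None:
    PRESETS[p.name] = p


# well-mixed relaxation to the stationary state: linear model on the
# separating line lambda_s = mu, matched to the logistic variant below
_register(Preset(
    name="fig3_linear",
    params=_mk((2.848, 1.0, 1.0, 2.848), (0.0, 0.0, 0.0)),
    description="linear kinetics on the separating line (lambda_s = mu = 2.848 lambda_e, "
                "lambda_d = lambda_e); init (0, 0.1, 0.479)",
    extras={"init": DensityTriple(0.0, 0.1, 0.479)},
))
_register(Preset(
    name="fig3_nonlinear",
    params=_mk((3.0, 1.0, 1.0, 1.0), (0.0, 0.0, 0.0), carrying=(1.0, 1.0, 1.0), growth="logistic"),
    description="logistic kinetics with lambda_s = 3 mu, unit carrying capacity; "
                "same initial condition and stationary state as fig3_linear",
    extras={"init": DensityTriple(0.0, 0.1, 0.479)},
))
# displacement moments of the delta initial condition
_register(Preset(
    name="fig4",
    params=_mk((1.0, 1.0, 1.0, 1.0), (1.0, 0.9, 0.2)),
    description="moment/ISF parameter set: all rates lambda_e, v- = 0.9 v+, D = 0.2 v+^2/lambda_e",
))
_register(Preset(
    name="fig4_equal",
    params=_mk((1.0, 1.0, 1.0, 1.0), (1.0, 1.0, 0.2)),
    description="equal-speed variant of fig4 (v- = v+): symmetric, diffusive long-time MSD",
))
# linear stability with attraction only
_register(Preset(
    name="fig7",
    params=_mk((1.0, 1.0, 1.0, 1.0), (1.0, 1.0, 2.0), interactions=(1.0, 0.0)),
    description="attraction-only dispersion: all rates lambda_e, kappa = 1/lambda_e, "
                "D = 2 v+^2/lambda_e (endpoint-marginal with rho_hat_plus = 1)",
    extras={"rho_hat_plus": 1.0},
))
# pattern formation regime shared by the separatrix and state-diagram scans
_register(Preset(
    name="fig8",
    params=_mk((0.1, 0.1, 1.0, 0.1), (0.0, 0.0, 0.001), interactions=(0.2, 0.05)),
    description="separatrix regime: lambda_s = lambda_d = mu = 0.1 lambda_e, "
                "kappa = 0.2, kappa_0 = 0.05 (1/lambda_e), D = 0.001 L^2 lambda_e; "
                "speeds scanned via (v_r, v_m)",
))
_register(Preset(
    name="fig9",
    params=_mk((0.1, 0.1, 1.0, 0.1), (0.1, 0.05, 0.001), interactions=(0.2, 0.05)),
    description="traveling-wave example: fig8 regime with v+ = 2 v- = 0.1 L lambda_e",
    n_x=128,
))
_register(Preset(
    name="fig10",
    params=PRESETS["fig8"].params,
    description="numerical state-diagram scan over (v_r, v_m) in the fig8 regime",
    n_x=128,
    n_steps=200_000,
))
_register(Preset(
    name="cc_table1",
    params=_mk(
        (_cc_dimless["lambda_s"], _cc_dimless["lambda_d"], 1.0, _cc_dimless["mu"]),
        (_cc_dimless["v_plus"], _cc_dimless["v_minus"], _cc_dimless["D"]),
    ),
    description="Caulobacter crescentus measured parameters, nondimensionalized "
                f"with L = {CC_DOMAIN_SI:g} m (SI values in presets.CC_TABLE_SI)",
    extras={"si": dict(CC_TABLE_SI), "L_si": CC_DOMAIN_SI},
))
_register(Preset(
    name="fig11",
    params=_mk(
        (_cc_dimless["lambda_s"], _cc_dimless["lambda_d"], 1.0, _cc_dimless["mu"]),
        (_cc_dimless["v_plus"], _cc_dimless["v_minus"], _cc_dimless["D"]),
        interactions=(10.0, 10.0),
        carrying=(0.1, 0.1, 0.1),
        growth="logistic",
    ),
    description="Caulobacter with logistic growth (mu < lambda_s), kappa = kappa_0 = "
                "10/lambda_e, carrying capacity 0.04 lambda_e/v+ in density units",
    n_x=128,
))


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
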