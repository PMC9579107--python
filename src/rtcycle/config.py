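"""Flat YAML configuration for model parameters and run options.

A run specification is a single mapping with exactly the keys below; unknown
keys are rejected with a message naming the offenders, as are missing or
ill-typed values.  Infinite carrying capacities round-trip as YAML ``.inf``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import yaml

from .params import (
    CarryingCapacity,
    Interactions,
    KineticRates,
    ModelParams,
    ParameterError,
    Transport,
)

__all__ = ["RunSpec", "load_config", "save_config", "CONFIG_KEYS"]

_PARAM_KEYS = (
    "lambda_s", "lambda_d", "lambda_e", "mu",
    "v_plus", "v_minus", "D",
    "kappa", "kappa_0",
    "rho_plus_c", "rho_0_c", "rho_minus_c",
    "growth_mode", "L",
)
_RUN_KEYS = ("n_x", "dt", "n_steps", "snapshot_stride", "noise_amplitude", "seed")
CONFIG_KEYS = _PARAM_KEYS + _RUN_KEYS

_RUN_DEFAULTS = {
    "n_x": 256,
    "dt": 1e-4,
    "n_steps": 1_000_000,
    "snapshot_stride": 10_000,
    "noise_amplitude": 1e-3,
    "seed": 0,
}


@dataclass(frozen=True)
class RunSpec:
    """Validated model parameters plus run options from one config file."""

    params: ModelParams
    L: float = 1.0
    n_x: int = 256
    dt: float = 1e-4
    n_steps: int = 1_000_000
    snapshot_stride: int = 10_000
    noise_amplitude: float = 1e-3
    seed: int = 0


def _as_float(key: str, value) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ParameterError(f"config key {key!r} must be a number, got {value!r}")
    return float(value)


def _as_int(key: str, value) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        if isinstance(value, float) and value.is_integer():
            return int(value)
        raise ParameterError(f"config key {key!r} must be an integer, got {value!r}")
    return int(value)


def spec_from_dict(data: dict) -> RunSpec:
    if not isinstance(data, dict):
        raise ParameterError("config must be a flat key-value mapping")
    unknown = sorted(set(data) - set(CONFIG_KEYS))
    if unknown:
        raise ParameterError(f"unknown config keys: {unknown}")
    missing = sorted(set(_PARAM_KEYS) - set(data))
    if missing:
        raise ParameterError(f"missing config keys: {missing}")
    growth = data["growth_mode"]
    if growth not in ("linear", "logistic"):
        raise ParameterError(f"growth_mode must be 'linear' or 'logistic', got {growth!r}")
    try:
        params = ModelParams(
            rates=KineticRates(
                lambda_s=_as_float("lambda_s", data["lambda_s"]),
                lambda_d=_as_float("lambda_d", data["lambda_d"]),
                lambda_e=_as_float("lambda_e", data["lambda_e"]),
                mu=_as_float("mu", data["mu"]),
            ),
            transport=Transport(
                v_plus=_as_float("v_plus", data["v_plus"]),
                v_minus=_as_float("v_minus", data["v_minus"]),
                D=_as_float("D", data["D"]),
            ),
            interactions=Interactions(
                kappa=_as_float("kappa", data["kappa"]),
                kappa_0=_as_float("kappa_0", data["kappa_0"]),
            ),
            carrying=CarryingCapacity(
                rho_plus_c=_as_float("rho_plus_c", data["rho_plus_c"]),
                rho_0_c=_as_float("rho_0_c", data["rho_0_c"]),
                rho_minus_c=_as_float("rho_minus_c", data["rho_minus_c"]),
            ),
            growth_mode=growth,
        )
    except ParameterError as e:
        raise ParameterError(f"invalid parameter value: {e}") from None
    run = dict(_RUN_DEFAULTS)
    for key in _RUN_KEYS:
        if key in data:
            run[key] = (_as_int if key in ("n_x", "n_steps", "snapshot_stride", "seed") else _as_float)(key, data[key])
    return RunSpec(params=params, L=_as_float("L", data["L"]), **run)


def spec_to_dict(spec: RunSpec) -> dict:
    p = spec.params
    return {
        "lambda_s": p.rates.lambda_s,
        "lambda_d": p.rates.lambda_d,
        "lambda_e": p.rates.lambda_e,
        "mu": p.rates.mu,
        "v_plus": p.transport.v_plus,
        "v_minus": p.transport.v_minus,
        "D": p.transport.D,
        "kappa": p.interactions.kappa,
        "kappa_0": p.interactions.kappa_0,
        "rho_plus_c": p.carrying.rho_plus_c,
        "rho_0_c": p.carrying.rho_0_c,
        "rho_minus_c": p.carrying.rho_minus_c,
        "growth_mode": p.growth_mode,
        "L": spec.L,
        "n_x": spec.n_x,
        "dt": spec.dt,
        "n_steps": spec.n_steps,
        "snapshot_stride": spec.snapshot_stride,
        "noise_amplitude": spec.noise_amplitude,
        "seed": spec.seed,
    }


def load_config(path) -> RunSpec:
    """Read and validate a YAML run specification."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return spec_from_dict(data)


def save_config(spec: RunSpec, path) -> None:
    """Write a run specification as flat YAML; round-trips losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
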