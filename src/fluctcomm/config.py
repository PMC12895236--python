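"""Experiment configuration: schema, defaults and validation.

Configs are flat JSON/YAML mappings.  Defaults follow the baseline protocol
(S=100, K=1, r*=1, gamma=0.05, tau=10, uniform competition, no immigration,
no cutoff) in units where one time unit is about one generation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .community import CommunityParams
from .errors import ConfigError
from .fitness import NoiseParams, gamma_from_sigma_tau, sigma_from_gamma_tau

__all__ = ["DEFAULTS", "validate_config", "community_params_from_config", "load_config"]

DEFAULTS = {
    "n_species": 100,
    "r_star": 1.0,
    "carrying_capacity": 1.0,
    "gamma": 0.05,
    "sigma_r": None,
    "tau": 10.0,
    "noise_mode": "ou",
    "epsilon": 0.0,
    "lam": 0.0,
    "n_ext": 0.0,
    "delta_r_star": 0.0,
    "n_patches": 1,
    "dispersal": 0.0,
    "coupling_mode": "total_rate",
    "horizon": 1000.0,
    "dt": None,
    "record_every": 1,
    "seed": 0,
}

_POSITIVE = ("r_star", "carrying_capacity", "tau", "horizon")
_NON_NEGATIVE = ("epsilon", "lam", "n_ext", "delta_r_star", "dispersal")


def load_config(source: Union[str, Path, dict, None]) -> dict:
    """Read a config mapping from a dict, a JSON/YAML file path, or text."""
    if source is None:
        return {}
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    if path.exists():
        text = path.read_text()
    else:
        text = str(source)
    try:
        # try JSON first: YAML 1.1 reads exponent floats like 1e-06 as strings
        data = json.loads(text)
    except json.JSONDecodeError:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError([f"could not parse config: {exc}"]) from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(["config must be a mapping"])
    return data


def validate_config(source=None) -> dict:
    """Fill defaults, check units/signs field-by-field, and echo derived
    quantities (mu, and whichever of sigma_r/gamma was omitted).

    Raises :class:`ConfigError` listing every offending field.
    """
    raw = load_config(source)
    problems = [f"unknown field {k!r}" for k in raw if k not in DEFAULTS]
    cfg = {**DEFAULTS, **{k: v for k, v in raw.items() if k in DEFAULTS}}

    for key in _POSITIVE:
        if not (isinstance(cfg[key], (int, float)) and cfg[key] > 0):
            problems.append(f"{key} must be a positive number, got {cfg[key]!r}")
    for key in _NON_NEGATIVE:
        if not (isinstance(cfg[key], (int, float)) and cfg[key] >= 0):
            problems.append(f"{key} must be a non-negative number, got {cfg[key]!r}")
    if not (isinstance(cfg["n_species"], int) and cfg["n_species"] >= 1):
        problems.append(f"n_species must be an integer >= 1, got {cfg['n_species']!r}")
    if not (isinstance(cfg["n_patches"], int) and cfg["n_patches"] >= 1):
        problems.append(f"n_patches must be an integer >= 1, got {cfg['n_patches']!r}")
    if cfg["noise_mode"] not in ("ou", "periodic", "white_limit"):
        problems.append(f"noise_mode must be ou/periodic/white_limit, got {cfg['noise_mode']!r}")
    if cfg["coupling_mode"] not in ("total_rate", "per_patch_rate"):
        problems.append(f"coupling_mode must be total_rate/per_patch_rate, got {cfg['coupling_mode']!r}")
    if cfg["dt"] is not None and not (isinstance(cfg["dt"], (int, float)) and cfg["dt"] > 0):
        problems.append(f"dt must be a positive number or null, got {cfg['dt']!r}")
    if "delta_r_star" in raw and raw["delta_r_star"] and cfg["delta_r_star"] > cfg["r_star"]:
        problems.append("delta_r_star must not exceed r_star")

    gamma, sigma_r, tau = cfg["gamma"], cfg["sigma_r"], cfg["tau"]
    if isinstance(tau, (int, float)) and tau > 0:
        if gamma is None and sigma_r is None:
            problems.append("one of gamma or sigma_r must be given")
        elif gamma is None:
            cfg["gamma"] = gamma_from_sigma_tau(sigma_r, tau)
        elif sigma_r is None:
            cfg["sigma_r"] = sigma_from_gamma_tau(gamma, tau)
        elif not np.isclose(gamma_from_sigma_tau(sigma_r, tau), gamma, rtol=1e-9):
            problems.append(
                f"inconsistent noise triple: gamma={gamma} but "
                f"2*sigma_r^2*tau={gamma_from_sigma_tau(sigma_r, tau)}"
            )
    if problems:
        raise ConfigError(problems)
    cfg["mu"] = cfg["r_star"] / cfg["carrying_capacity"]
    return cfg


def community_params_from_config(cfg: dict, mean_fitness=None) -> CommunityParams:
    """Build CommunityParams from a validated config."""
    noise = NoiseParams(
        mean_fitness=cfg["r_star"] if mean_fitness is None else mean_fitness,
        gamma=cfg["gamma"],
        tau=cfg["tau"],
        mode=cfg["noise_mode"],
    )
    return CommunityParams(
        n_species=cfg["n_species"],
        r_star=cfg["r_star"],
        carrying_capacity=cfg["carrying_capacity"],
        epsilon=cfg["epsilon"],
        lam=cfg["lam"],
        n_ext=cfg["n_ext"],
        noise=noise,
    )
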