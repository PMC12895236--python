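"""Fluctuating per-capita growth-rate ("fitness") processes.

Species fitnesses are modelled as independent stationary processes with mean
``r_i*``, standard deviation ``sigma_r`` and autocorrelation time ``tau``.
Three modes are supported:

``ou``
    Ornstein-Uhlenbeck colored noise, generated with the *exact* discrete
    transition so that step size never biases stationary statistics.
``periodic``
    Deterministic oscillation ``r*(t) = r* + sqrt(2)*sigma_r*cos(t/tau - phi)``
    whose time-averaged variance equals ``sigma_r**2``.
``white_limit``
    The fast-environment limit (tau -> 0 at fixed gamma).  Paths of this mode
    cannot be sampled on a grid; integrators treat it as a Stratonovich
    diffusion term of amplitude ``sqrt(gamma)``.

The compound parameter ``gamma = 2*sigma_r**2*tau`` sets the pace of
stochastic exclusion and is used interchangeably with ``sigma_r`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .errors import ParameterError

__all__ = [
    "NoiseParams",
    "gamma_from_sigma_tau",
    "sigma_from_gamma_tau",
    "sample_fitness_paths",
    "periodic_fitness",
    "draw_mean_fitnesses",
    "standard_increments",
    "ou_step_factors",
]

ArrayLike = Union[float, np.ndarray]


def gamma_from_sigma_tau(sigma_r: float, tau: float) -> float:
    """Exclusion rate ``gamma = 2*sigma_r**2*tau``."""
    if tau <= 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    if sigma_r < 0:
        raise ParameterError(f"sigma_r must be non-negative, got {sigma_r}")
    return 2.0 * sigma_r**2 * tau


def sigma_from_gamma_tau(gamma: float, tau: float) -> float:
    """Stationary fitness s.d. implied by ``(gamma, tau)``: sqrt(gamma/(2*tau))."""
    if tau <= 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    if gamma < 0:
        raise ParameterError(f"gamma must be non-negative, got {gamma}")
    return float(np.sqrt(gamma / (2.0 * tau)))


@dataclass
class NoiseParams:
    """Statistics of the fitness process.

    Exactly one of ``sigma_r`` / ``gamma`` may be omitted; the other is then
    derived through ``gamma = 2*sigma_r**2*tau``.  If both are supplied they
    must be consistent.

    Parameters
    ----------
    mean_fitness:
        Expected fitness ``r_i*`` (1/time); a scalar for time-average-neutral
        communities or a per-species vector.
    sigma_r:
        Stationary fitness standard deviation (1/time).
    gamma:
        Exclusion rate ``2*sigma_r**2*tau`` (1/time).
    tau:
        Autocorrelation time (time).  Required for ``ou`` and ``periodic``.
    mode:
        One of ``{"ou", "periodic", "white_limit"}``.
    phases:
        Per-species phase (radians); only used in ``periodic`` mode.  If
        omitted, phases are drawn uniformly on [0, 2*pi).
    """

    mean_fitness: ArrayLike = 1.0
    sigma_r: Optional[float] = None
    gamma: Optional[float] = None
    tau: float = 10.0
    mode: str = "ou"
    phases: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.mode not in ("ou", "periodic", "white_limit"):
            raise ParameterError(f"unknown noise mode {self.mode!r}")
        if self.mode != "white_limit" and self.tau <= 0:
            raise ParameterError(f"tau must be positive, got {self.tau}")
        if self.sigma_r is None and self.gamma is None:
            raise ParameterError("one of sigma_r or gamma must be given")
        if self.sigma_r is None:
            if self.mode == "white_limit":
                self.sigma_r = float("inf") if self.gamma > 0 else 0.0
            else:
                self.sigma_r = sigma_from_gamma_tau(self.gamma, self.tau)
        elif self.gamma is None:
            if self.mode == "white_limit":
                raise ParameterError("white_limit mode requires gamma, not sigma_r")
            self.gamma = gamma_from_sigma_tau(self.sigma_r, self.tau)
        else:
            expected = gamma_from_sigma_tau(self.sigma_r, self.tau)
            if not np.isclose(expected, self.gamma, rtol=1e-10, atol=1e-300):
                raise ParameterError(
                    f"inconsistent noise parameters: gamma={self.gamma} but "
                    f"2*sigma_r^2*tau={expected}"
                )
        if self.sigma_r < 0:
            raise ParameterError("sigma_r must be non-negative")
        if not np.all(np.isfinite(np.asarray(self.mean_fitness, dtype=float))):
            raise ParameterError("mean_fitness must be finite")

    def mean_fitness_vector(self, n_species: int) -> np.ndarray:
        """Broadcast ``mean_fitness`` to a length-``n_species`` vector."""
        r = np.asarray(self.mean_fitness, dtype=float)
        if r.ndim == 0:
            return np.full(n_species, float(r))
        if r.shape != (n_species,):
            raise ParameterError(
                f"mean_fitness has shape {r.shape}, expected ({n_species},)"
            )
        return r.copy()

    def with_tau(self, tau: float) -> "NoiseParams":
        """Same exclusion rate, different correlation time (sigma_r re-derived)."""
        return replace(self, tau=tau, sigma_r=None, gamma=self.gamma)


def ou_step_factors(tau: float, sigma_r: float, dt: float):
    """Exact OU transition coefficients over a step ``dt``.

    r(t+dt) = r* + alpha*(r(t) - r*) + beta*xi,  xi ~ N(0,1), with
    alpha = exp(-dt/tau) and beta = sigma_r*sqrt(1 - alpha^2), so the
    stationary law N(r*, sigma_r^2) is preserved exactly for any dt.
    """
    alpha = float(np.exp(-dt / tau))
    beta = float(sigma_r * np.sqrt(1.0 - alpha**2))
    return alpha, beta


def standard_increments(n_steps: int, n_species: int, seed) -> np.ndarray:
    """Standard-normal increment stream (n_steps, n_species) for a given seed.

    Deterministic in ``seed``: two calls with the same seed are bitwise
    identical, which is what lets runs with different ``tau`` share the same
    underlying randomness.
    """
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_steps, n_species))


def sample_fitness_paths(
    params: NoiseParams,
    n_species: int,
    times: np.ndarray,
    seed=None,
    init: str = "stationary",
    increments: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Sample OU fitness paths on a time grid.

    Parameters
    ----------
    params:
        Noise parameters; ``mode`` must be ``"ou"``.
    n_species:
        Number of independent species paths.
    times:
        Strictly increasing sample times; the first entry carries the initial
        condition.
    seed:
        Seed for the increment stream (ignored when ``increments`` is given).
    init:
        ``"stationary"`` draws r(0) ~ N(r*, sigma_r^2); ``"mean"`` sets
        r(0) = r*.
    increments:
        Optional pre-drawn standard normals of shape
        ``(len(times) - 1 + (init=="stationary"), n_species)``; lets several
        calls with different ``tau`` reuse identical randomness.

    Returns
    -------
    ndarray of shape (len(times), n_species).
    """
    if params.mode == "white_limit":
        raise ParameterError(
            "white_limit paths are not defined on a grid; integrators handle "
            "this mode as a diffusion term"
        )
    if params.mode == "periodic":
        raise ParameterError("use periodic_fitness for periodic mode")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ParameterError("times must be a 1-d array")
    dts = np.diff(times)
    if np.any(dts <= 0):
        raise ParameterError("times must be strictly increasing")
    n_steps = len(times) - 1
    need = n_steps + (1 if init == "stationary" else 0)
    if increments is None:
        increments = standard_increments(need, n_species, seed)
    increments = np.asarray(increments, dtype=float)
    if increments.shape[0] < need or increments.shape[1] != n_species:
        raise ParameterError(
            f"increments has shape {increments.shape}, need at least "
            f"({need}, {n_species})"
        )

    rstar = params.mean_fitness_vector(n_species)
    out = np.empty((len(times), n_species))
    k = 0
    if init == "stationary":
        out[0] = rstar + params.sigma_r * increments[0]
        k = 1
    elif init == "mean":
        out[0] = rstar
    else:
        raise ParameterError(f"unknown init {init!r}")
    for j, dt in enumerate(dts):
        alpha, beta = ou_step_factors(params.tau, params.sigma_r, dt)
        out[j + 1] = rstar + alpha * (out[j] - rstar) + beta * increments[k + j]
    return out


def periodic_fitness(
    params: NoiseParams,
    n_species: int,
    times: np.ndarray,
    seed=None,
) -> np.ndarray:
    """Deterministic periodic fitness r_i(t) = r_i* + sqrt(2)*sigma_r*cos(t/tau - phi_i).

    The sqrt(2) amplitude makes the time-averaged variance over whole periods
    equal to sigma_r^2, matching the OU stationary variance.
    """
    times = np.asarray(times, dtype=float)
    rstar = params.mean_fitness_vector(n_species)
    if params.phases is not None:
        phases = np.asarray(params.phases, dtype=float)
        if phases.shape != (n_species,):
            raise ParameterError(
                f"phases has shape {phases.shape}, expected ({n_species},)"
            )
    else:
        phases = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi, n_species)
    amp = np.sqrt(2.0) * params.sigma_r
    return rstar[None, :] + amp * np.cos(times[:, None] / params.tau - phases[None, :])


def draw_mean_fitnesses(
    r_star: float, delta_r_star: float, n_species: int, seed=None
) -> np.ndarray:
    """Draw per-species mean fitnesses uniformly on [r* - dr*, r* + dr*].

    ``delta_r_star = 0`` returns the time-average-neutral vector (all r*).
    """
    if delta_r_star < 0:
        raise ParameterError("delta_r_star must be non-negative")
    if delta_r_star > r_star:
        raise ParameterError(
            "delta_r_star must not exceed r_star (mean fitnesses must stay positive)"
        )
    if delta_r_star == 0:
        return np.full(n_species, float(r_star))
    rng = np.random.default_rng(seed)
    return rng.uniform(r_star - delta_r_star, r_star + delta_r_star, n_species)
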