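"""Single-patch community dynamics.

Integrates the growth equation

    dn_i/dt = n_i*(r_i(t) - mu*N - eps*n_i) + lam,      N = sum_j n_j,

with fluctuating fitnesses r_i(t), uniform competition mu = r*/K, excess
self-regulation eps, constant immigration lam, and an optional extinction
cutoff n_ext below which abundances are set to zero.

The integrator uses operator splitting per step: (i) exact OU fitness update,
(ii) multiplicative growth n <- n*exp[(r_mid - mu*N - eps*n)*dt] with the
midpoint fitness, (iii) additive immigration n <- n + lam*dt, (iv) extinction
cutoff.  The multiplicative update preserves positivity exactly and makes the
even neutral community an exact fixed point.  The model is an ODE with random
coefficients (colored noise), so no Ito/Stratonovich ambiguity arises except
in the explicit white-noise limit, which is treated as Stratonovich.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import logsumexp

from .errors import IntegrationError, ParameterError
from .fitness import NoiseParams, ou_step_factors

__all__ = [
    "CommunityParams",
    "Trajectory",
    "simulate_community",
    "simulate_ensemble",
    "replicator_solution",
    "focal_delta_r",
    "integrated_fitness",
]


@dataclass
class CommunityParams:
    """Base parameters of the growth equation.

    Attributes
    ----------
    n_species:
        Species-pool size S.
    r_star:
        Community-mean fitness r* (1/time); per-species means live in
        ``noise.mean_fitness``.
    carrying_capacity:
        K = r*/mu; the deterministic neutral equilibrium of total abundance.
    epsilon:
        Excess self-regulation (1/(abundance*time)); 0 = uniform competition.
    lam:
        Constant immigration rate (abundance/time).
    n_ext:
        Extinction threshold (abundance); 0 disables the cutoff.
    noise:
        Fitness-process parameters.
    """

    n_species: int = 100
    r_star: float = 1.0
    carrying_capacity: float = 1.0
    epsilon: float = 0.0
    lam: float = 0.0
    n_ext: float = 0.0
    noise: NoiseParams = field(default_factory=lambda: NoiseParams(gamma=0.05, tau=10.0))

    def __post_init__(self):
        if self.n_species < 1:
            raise ParameterError("n_species must be >= 1")
        if self.carrying_capacity <= 0:
            raise ParameterError("carrying_capacity must be positive")
        if self.epsilon < 0 or self.lam < 0 or self.n_ext < 0:
            raise ParameterError("epsilon, lam and n_ext must be non-negative")

    @property
    def mu(self) -> float:
        """Uniform competition strength mu = r*/K."""
        return self.r_star / self.carrying_capacity

    def default_dt(self) -> float:
        """Step resolving both the noise and the growth timescale."""
        tau = self.noise.tau if self.noise.mode != "white_limit" else np.inf
        return min(tau, 1.0 / self.r_star) / 20.0

    def even_init(self) -> np.ndarray:
        """Perfectly even initial community, n_i = K/S."""
        return np.full(self.n_species, self.carrying_capacity / self.n_species)


@dataclass
class Trajectory:
    """Recorded community time series (times x species)."""

    times: np.ndarray
    abundance: np.ndarray
    fitness: np.ndarray
    params: CommunityParams
    seed: Optional[int] = None

    def __post_init__(self):
        if self.abundance.shape != self.fitness.shape:
            raise ParameterError("abundance and fitness grids are misaligned")
        if self.abundance.shape[0] != len(self.times):
            raise ParameterError("times and abundance grids are misaligned")

    @property
    def total_abundance(self) -> np.ndarray:
        return self.abundance.sum(axis=1)

    @property
    def relative_abundance(self) -> np.ndarray:
        N = self.total_abundance
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(N[:, None] > 0, self.abundance / N[:, None], 0.0)

    @property
    def dt_sample(self) -> float:
        return float(self.times[1] - self.times[0])

    def after(self, burn_in: float) -> "Trajectory":
        """Sub-trajectory with times >= burn_in (clock reset not applied)."""
        m = self.times >= burn_in
        return Trajectory(self.times[m], self.abundance[m], self.fitness[m],
                          self.params, self.seed)


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _resolve_dt(params: CommunityParams, horizon: float, dt: Optional[float]):
    if dt is None:
        dt = params.default_dt()
    if dt <= 0 or horizon <= 0:
        raise ParameterError("dt and horizon must be positive")
    if params.noise.mode != "white_limit" and dt > params.noise.tau:
        warnings.warn(
            f"dt={dt} exceeds the noise correlation time tau={params.noise.tau}; "
            "fitness fluctuations are under-resolved",
            stacklevel=3,
        )
    n_steps = max(1, int(round(horizon / dt)))
    return dt, n_steps


def _step_block(n, r_prev, r_new, mode_white, rstar, mu, eps, lam, n_ext, dt,
                sqrt_gamma_dt, xi_white):
    """Advance an (R, S) abundance block by one split step.  Mutates ``n``."""
    N = n.sum(axis=1, keepdims=True)
    if mode_white:
        # Stratonovich white noise enters the log-abundance increment directly
        expo = (rstar - mu * N - eps * n) * dt + sqrt_gamma_dt * xi_white
    else:
        r_mid = 0.5 * (r_prev + r_new)
        expo = (r_mid - mu * N - eps * n) * dt
    n *= np.exp(expo)
    if lam > 0:
        n += lam * dt
    if n_ext > 0:
        n[n < n_ext] = 0.0
    return n


def _simulate_block(
    params: CommunityParams,
    n0: np.ndarray,           # (R, S)
    horizon: float,
    dt: Optional[float],
    record_every: int,
    rng: np.random.Generator,
    fitness_init: str,
    reduce: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    stop_when: Optional[Callable[[np.ndarray], bool]] = None,
):
    """Core loop shared by single runs and vectorized ensembles.

    Returns (times, abundance records, fitness records) with record arrays of
    shape (T, R, S), or (times, reduced records) when ``reduce`` is given.
    """
    dt, n_steps = _resolve_dt(params, horizon, dt)
    R, S = n0.shape
    noise = params.noise
    rstar = noise.mean_fitness_vector(S)[None, :]
    mu, eps, lam, n_ext = params.mu, params.epsilon, params.lam, params.n_ext

    mode = noise.mode
    if mode == "ou":
        alpha, beta = ou_step_factors(noise.tau, noise.sigma_r, dt)
        if fitness_init == "stationary":
            r = rstar + noise.sigma_r * rng.standard_normal((R, S))
        elif fitness_init == "mean":
            r = np.broadcast_to(rstar, (R, S)).copy()
        else:
            raise ParameterError(f"unknown fitness_init {fitness_init!r}")
    elif mode == "periodic":
        if noise.phases is not None:
            phases = np.broadcast_to(np.asarray(noise.phases, float), (R, S))
        else:
            phases = rng.uniform(0.0, 2.0 * np.pi, (R, S))
        amp = np.sqrt(2.0) * noise.sigma_r
        r = rstar + amp * np.cos(-phases)
    elif mode == "white_limit":
        r = np.broadcast_to(rstar, (R, S)).copy()
    else:  # pragma: no cover
        raise ParameterError(f"unknown noise mode {mode!r}")

    sqrt_gamma_dt = np.sqrt(noise.gamma * dt) if mode == "white_limit" else 0.0

    n = np.array(n0, dtype=float)
    if np.any(n < 0):
        raise ParameterError("initial abundances must be non-negative")
    if n_ext > 0:
        n[n < n_ext] = 0.0

    n_records = n_steps // record_every + 1
    times = np.empty(n_records)
    if reduce is None:
        rec_n = np.empty((n_records, R, S))
        rec_r = np.empty((n_records, R, S))
        rec_n[0], rec_r[0] = n, r
    else:
        first = np.asarray(reduce(n))
        red = np.empty((n_records,) + first.shape)
        red[0] = first
    times[0] = 0.0

    k = 1
    stopped = False
    for step in range(1, n_steps + 1):
        t = step * dt
        r_prev = r
        xi = None
        if mode == "ou":
            r = rstar + alpha * (r - rstar) + beta * rng.standard_normal((R, S))
        elif mode == "periodic":
            r = rstar + amp * np.cos(t / noise.tau - phases)
        else:
            xi = rng.standard_normal((R, S))
        _step_block(n, r_prev, r, mode == "white_limit", rstar, mu, eps, lam,
                    n_ext, dt, sqrt_gamma_dt, xi)
        if step % record_every == 0:
            if not np.all(np.isfinite(n)):
                raise IntegrationError(
                    f"non-finite abundance at step {step} (t={t:g}); "
                    "reduce dt or check parameters"
                )
            times[k] = t
            if reduce is None:
                rec_n[k], rec_r[k] = n, r
            else:
                red[k] = reduce(n)
                if stop_when is not None and stop_when(red[k]):
                    k += 1
                    stopped = True
                    break
            k += 1
    if stopped or k < n_records:
        times = times[:k]
        if reduce is None:
            rec_n, rec_r = rec_n[:k], rec_r[:k]
        else:
            red = red[:k]
    if reduce is None:
        return times, rec_n, rec_r
    return times, red


def simulate_community(
    params: CommunityParams,
    init: Optional[np.ndarray] = None,
    horizon: float = 1000.0,
    dt: Optional[float] = None,
    record_every: int = 1,
    seed=None,
    fitness_init: str = "stationary",
) -> Trajectory:
    """Simulate one community realization.

    Parameters
    ----------
    init:
        Initial abundances (default: even community K/S).
    horizon, dt:
        Total time and step; ``dt`` defaults to ``min(tau, 1/r*)/20``.
    record_every:
        Record every k-th step (plus the initial state).
    seed:
        Master seed; the per-run stream is spawned from it so that a
        metacommunity with M=1 reproduces the same realization.
    fitness_init:
        ``"stationary"`` (default) or ``"mean"`` (r(0) = r*).
    """
    if init is None:
        init = params.even_init()
    init = np.asarray(init, dtype=float)
    if init.shape != (params.n_species,):
        raise ParameterError(
            f"init has shape {init.shape}, expected ({params.n_species},)"
        )
    rng = np.random.default_rng(_as_seed_sequence(seed).spawn(1)[0])
    times, rec_n, rec_r = _simulate_block(
        params, init[None, :], horizon, dt, record_every, rng, fitness_init
    )
    return Trajectory(times, rec_n[:, 0, :], rec_r[:, 0, :], params, seed)


def simulate_ensemble(
    params: CommunityParams,
    n_runs: int,
    horizon: float = 1000.0,
    dt: Optional[float] = None,
    record_every: int = 1,
    seed=None,
    fitness_init: str = "stationary",
    init: Optional[np.ndarray] = None,
    reduce: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    stop_when: Optional[Callable[[np.ndarray], bool]] = None,
):
    """Simulate ``n_runs`` independent replicate communities in lock-step.

    With ``reduce`` given (a map from the (runs, species) abundance block to a
    per-record summary, e.g. effective richness per run), only the reduced
    records are stored, so large ensembles stay memory-bounded.  ``stop_when``
    is checked on each reduced record and truncates the run early.

    Returns ``(times, abundance, fitness)`` with shape (T, runs, species), or
    ``(times, reduced)`` when ``reduce`` is given.
    """
    if init is None:
        init = params.even_init()
    n0 = np.broadcast_to(np.asarray(init, float), (n_runs, params.n_species))
    rng = np.random.default_rng(seed)
    return _simulate_block(
        params, n0, horizon, dt, record_every, rng, fitness_init,
        reduce=reduce, stop_when=stop_when,
    )


def integrated_fitness(fitness: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Cumulative time-integrated fitnesses R_i(t) (trapezoidal), R_i(0)=0."""
    fitness = np.asarray(fitness, float)
    times = np.asarray(times, float)
    return cumulative_trapezoid(fitness, times, axis=0, initial=0.0)


def replicator_solution(
    fitness: np.ndarray, times: np.ndarray, p0: np.ndarray, atol: float = 1e-8
) -> np.ndarray:
    """Exact relative-abundance solution p_i(t) = p_i(0) e^{R_i(t)} / Z(t).

    Valid for uniform competition without immigration or cutoff, where
    composition decouples from total abundance.  Computed with log-sum-exp
    for numerical safety; each output row sums to 1.
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > max(atol, 1e-6):
        raise ParameterError(f"p0 is not on the simplex (sum={p0.sum()})")
    R = integrated_fitness(fitness, times)
    with np.errstate(divide="ignore"):
        logw = np.log(p0)[None, :] + R
    logZ = logsumexp(logw, axis=1, keepdims=True)
    return np.exp(logw - logZ)


def focal_delta_r(trajectory: Trajectory, focal: int) -> np.ndarray:
    """Fitness gap Delta r_i(t) = r_i(t) - rho_{\\i}(t) of a focal species.

    rho_{\\i} is the mean fitness of the complementary sub-community, weighted
    by within-subcommunity relative abundances.  For S=2 this reduces to
    r_1 - r_2 exactly.  Drives dp_i/dt = Delta r_i * p_i * (1 - p_i) under
    uniform competition.
    """
    S = trajectory.params.n_species
    if S < 2:
        raise ParameterError("focal_delta_r requires at least 2 species")
    if not (0 <= focal < S):
        raise ParameterError(f"focal index {focal} out of range for S={S}")
    n = trajectory.abundance
    r = trajectory.fitness
    mask = np.ones(S, dtype=bool)
    mask[focal] = False
    n_rest = n[:, mask]
    w = n_rest.sum(axis=1)
    if np.any(w <= 0):
        raise ParameterError("complementary sub-community has zero abundance")
    rho_rest = (r[:, mask] * n_rest).sum(axis=1) / w
    return r[:, focal] - rho_rest
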