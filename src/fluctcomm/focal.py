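"""Focal-species effective model and generalised-inverse-Gaussian SAD.

A focal species embedded in a large community experiences an effective
fluctuating environment:

    dn/dt = n*(r_eff(t) - eps*n) + lam,

with r_eff an OU process whose statistics approximate those of
r_i(t) - mu*N(t) in the full model.  In the fast-environment limit the
stationary abundance distribution is a generalised inverse Gaussian,

    P(n) = C * n^(-nu) * exp(-n/a - b/n),

with nu = 1 - 2*r_eff*/gamma_eff, a = gamma_eff/(2*eps), b = 2*lam/gamma_eff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, special, stats

from .community import Trajectory
from .errors import EstimationError, FitError, NormalizationError, ParameterError

__all__ = [
    "EffectiveParams",
    "GIGParams",
    "GIGFit",
    "estimate_ou_stats",
    "estimate_effective_params",
    "gig_shape",
    "gig_logpdf",
    "gig_pdf",
    "gig_rvs",
    "gig_cdf",
    "simulate_focal",
    "fit_gig",
]


@dataclass
class EffectiveParams:
    """Noise statistics of the focal species' effective environment."""

    r_eff: float
    sigma_eff: float
    tau_eff: float

    def __post_init__(self):
        if self.sigma_eff < 0:
            raise ParameterError("sigma_eff must be non-negative")
        if self.tau_eff <= 0:
            raise ParameterError("tau_eff must be positive")

    @property
    def gamma_eff(self) -> float:
        return 2.0 * self.sigma_eff**2 * self.tau_eff


# ---------------------------------------------------------------------------
# effective-parameter estimation
# ---------------------------------------------------------------------------

def _acf_fft(x: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation of a 1-d series via FFT."""
    x = x - x.mean()
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    if acov[0] <= 0:
        return np.ones(1)
    return acov / acov[0]


def integrated_autocorrelation_time(x: np.ndarray, dt: float) -> float:
    """Integrated autocorrelation time with a first-zero-crossing cutoff.

    tau_int = dt * (1/2 + sum_{k=1}^{K-1} rho_k), where K is the first lag at
    which the normalized autocorrelation crosses zero.  Exact for an OU
    process in the limit of fine sampling (integral of exp(-t/tau) = tau).
    """
    rho = _acf_fft(np.asarray(x, dtype=float))
    neg = np.nonzero(rho < 0)[0]
    cut = neg[0] if len(neg) else len(rho)
    return dt * (0.5 + rho[1:cut].sum())


def estimate_ou_stats(x: np.ndarray, dt: float) -> Tuple[float, float, float]:
    """(mean, s.d., integrated autocorrelation time) of a stationary series."""
    x = np.asarray(x, dtype=float)
    return float(x.mean()), float(x.std(ddof=1)), float(
        integrated_autocorrelation_time(x, dt)
    )


def tau_by_exponential_fit(x: np.ndarray, dt: float, max_lag: Optional[int] = None) -> float:
    """Cross-check estimator: least-squares exponential fit to the ACF."""
    rho = _acf_fft(np.asarray(x, dtype=float))
    if max_lag is None:
        neg = np.nonzero(rho < 0.05)[0]
        max_lag = int(neg[0]) if len(neg) else len(rho)
    max_lag = max(max_lag, 3)
    lags = np.arange(1, max_lag)
    y = rho[1:max_lag]
    m = y > 0
    if m.sum() < 2:
        raise EstimationError("autocorrelation decays too fast for an exponential fit")
    slope = np.polyfit(lags[m] * dt, np.log(y[m]), 1)[0]
    if slope >= 0:
        raise EstimationError("non-decaying autocorrelation")
    return -1.0 / slope


def estimate_effective_params(
    trajectory: Trajectory,
    focal: Optional[int] = None,
    burn_in_frac: float = 0.2,
    min_length_taus: float = 50.0,
) -> EffectiveParams:
    """Estimate the focal species' effective noise statistics from a trajectory.

    Builds x_i(t) = r_i(t) - mu*N(t) after discarding a burn-in fraction, then
    takes r_eff* = mean, sigma_eff = s.d., and tau_eff as the integrated
    autocorrelation time (first-zero-crossing cutoff).  With ``focal=None``
    the statistics are pooled (averaged) over all species, which is exact
    under species exchangeability.
    """
    t0 = trajectory.times[0] + burn_in_frac * (trajectory.times[-1] - trajectory.times[0])
    traj = trajectory.after(t0)
    dt = traj.dt_sample
    mu = traj.params.mu
    x = traj.fitness - mu * traj.total_abundance[:, None]
    if focal is not None:
        cols = [focal]
    else:
        cols = range(x.shape[1])
    means, vars_, taus = [], [], []
    for j in cols:
        m, s, tau = estimate_ou_stats(x[:, j], dt)
        means.append(m)
        vars_.append(s**2)
        taus.append(tau)
    tau_eff = float(np.mean(taus))
    span = traj.times[-1] - traj.times[0]
    if span < min_length_taus * tau_eff:
        raise EstimationError(
            f"series length {span:g} < {min_length_taus:g} x tau_eff={tau_eff:g}; "
            "estimate unreliable"
        )
    return EffectiveParams(
        r_eff=float(np.mean(means)),
        sigma_eff=float(np.sqrt(np.mean(vars_))),
        tau_eff=tau_eff,
    )


# ---------------------------------------------------------------------------
# GIG stationary distribution
# ---------------------------------------------------------------------------

@dataclass
class GIGParams:
    """Shape triple of the bent-power-law SAD P(n) ~ n^(-nu) e^(-n/a - b/n).

    ``a = inf`` (no upper bend; requires nu > 1) and ``b = 0`` (no lower
    bend; requires nu < 1) are admissible limits; outside those ranges the
    density is improper.
    """

    nu: float
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b < 0:
            raise ParameterError("GIG scales require a > 0 and b >= 0")

    @property
    def is_proper(self) -> bool:
        if self.b == 0 and math.isinf(self.a):
            return False
        if self.b == 0:
            return self.nu < 1.0
        if math.isinf(self.a):
            return self.nu > 1.0
        return True

    def describe_degenerate(self) -> str:
        if self.b == 0 and math.isinf(self.a):
            return "pure power law (a=inf, b=0)"
        if self.b == 0:
            return f"gamma limit (b=0) requires nu < 1, got nu={self.nu}"
        return f"inverse-gamma limit (a=inf) requires nu > 1, got nu={self.nu}"

    def classify(self) -> str:
        """Coarse shape class: exclusion / buffered / stabilised / lognormal-like."""
        if not self.is_proper:
            return "improper"
        if self.nu < 0:
            return "gamma-like (stabilised)"
        z = 2.0 * math.sqrt(self.b / self.a) if not math.isinf(self.a) else 0.0
        if z > 1.0:
            return "lognormal-like (buffered-and-stabilised)"
        if self.nu > 1.2:
            return "steep power law (buffered)"
        return "wide power law (exclusion)"


def gig_shape(eff: EffectiveParams, epsilon: float, lam: float) -> GIGParams:
    """Map effective parameters to the fast-limit SAD shape.

    nu = 1 - 2*r_eff*/gamma_eff; a = gamma_eff/(2*eps); b = 2*lam/gamma_eff.
    eps=0 yields a=inf (proper only for nu > 1); lam=0 yields b=0 (proper
    only for nu < 1).
    """
    g = eff.gamma_eff
    if g <= 0:
        raise ParameterError("gig_shape requires gamma_eff > 0")
    if epsilon < 0 or lam < 0:
        raise ParameterError("epsilon and lam must be non-negative")
    nu = 1.0 - 2.0 * eff.r_eff / g
    a = g / (2.0 * epsilon) if epsilon > 0 else float("inf")
    b = 2.0 * lam / g
    return GIGParams(nu=nu, a=a, b=b)


def _gig_log_norm(shape: GIGParams) -> float:
    """log of the normalization constant C of P(n) = C n^(-nu) e^(-n/a - b/n)."""
    nu, a, b = shape.nu, shape.a, shape.b
    if not shape.is_proper:
        raise NormalizationError(
            f"improper GIG parameters: {shape.describe_degenerate()}"
        )
    if b == 0:  # gamma limit: C = 1 / (Gamma(1-nu) a^(1-nu))
        return -special.gammaln(1.0 - nu) - (1.0 - nu) * math.log(a)
    if math.isinf(a):  # inverse-gamma limit: C = b^(nu-1) / Gamma(nu-1)
        return (nu - 1.0) * math.log(b) - special.gammaln(nu - 1.0)
    # int n^{-nu} e^{-n/a - b/n} dn = 2 (a b)^{(1-nu)/2} K_{1-nu}(2 sqrt(b/a))
    z = 2.0 * math.sqrt(b / a)
    p = 1.0 - nu
    log_kve = math.log(special.kve(p, z))  # kve = K_p(z) e^z
    return -(math.log(2.0) + 0.5 * p * math.log(a * b) + log_kve - z)


def gig_logpdf(n, shape: GIGParams) -> np.ndarray:
    """Log-density of the bent power law; -inf for n <= 0."""
    n = np.asarray(n, dtype=float)
    logc = _gig_log_norm(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            n > 0,
            logc - shape.nu * np.log(n)
            - (n / shape.a if not math.isinf(shape.a) else 0.0)
            - np.where(n > 0, shape.b / n, np.inf),
            -np.inf,
        )
    return out


def gig_pdf(n, shape: GIGParams) -> np.ndarray:
    """Density of the bent power law (generalised inverse Gaussian)."""
    return np.exp(gig_logpdf(n, shape))


def _as_scipy(shape: GIGParams):
    """Map (nu, a, b) to a frozen scipy distribution."""
    nu, a, b = shape.nu, shape.a, shape.b
    if not shape.is_proper:
        raise NormalizationError(
            f"improper GIG parameters: {shape.describe_degenerate()}"
        )
    if b == 0:
        return stats.gamma(1.0 - nu, scale=a)
    if math.isinf(a):
        return stats.invgamma(nu - 1.0, scale=b)
    return stats.geninvgauss(1.0 - nu, 2.0 * math.sqrt(b / a), scale=math.sqrt(a * b))


def gig_cdf(n, shape: GIGParams) -> np.ndarray:
    return _as_scipy(shape).cdf(np.asarray(n, dtype=float))


def gig_rvs(shape: GIGParams, size: int, seed=None) -> np.ndarray:
    return _as_scipy(shape).rvs(size=size, random_state=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# focal-species simulation
# ---------------------------------------------------------------------------

def simulate_focal(
    eff: EffectiveParams,
    epsilon: float,
    lam: float,
    horizon: float,
    dt: Optional[float] = None,
    seed=None,
    fast_limit: bool = False,
    record_every: int = 1,
    init: Optional[float] = None,
    n_chains: int = 1,
):
    """Integrate the one-species effective equation dn/dt = n(r_eff - eps*n) + lam.

    In the default (colored-noise) mode r_eff(t) is an exact-transition OU
    process and the abundance is advanced by the same multiplicative splitting
    as the full community.  In ``fast_limit`` mode the noise is Stratonovich
    white noise of amplitude sqrt(gamma_eff); the integration is done in log
    abundance (where the noise is additive and Stratonovich = Ito) with a Heun
    predictor-corrector, so positivity is automatic and the stationary
    histogram converges to ``gig_pdf``.

    Returns ``(times, n)`` with ``n`` of shape (T,) for one chain or
    (T, n_chains) otherwise.
    """
    if epsilon < 0 or lam < 0:
        raise ParameterError("epsilon and lam must be non-negative")
    if dt is None:
        dt = 0.01 if fast_limit else min(eff.tau_eff, 1.0) / 20.0
    n_steps = max(1, int(round(horizon / dt)))
    rng = np.random.default_rng(seed)
    g = eff.gamma_eff

    if init is None:
        if epsilon > 0 and eff.r_eff > 0:
            init = eff.r_eff / epsilon
        elif epsilon > 0:
            init = math.sqrt(max(lam, 1e-12) / epsilon)
        else:
            init = 1.0
    x0 = np.full(n_chains, float(init))

    n_records = n_steps // record_every + 1
    times = np.empty(n_records)
    rec = np.empty((n_records, n_chains))
    times[0] = 0.0

    if fast_limit:
        if g <= 0:
            raise ParameterError("fast_limit requires gamma_eff > 0")
        sq = math.sqrt(g * dt)
        y = np.log(x0)
        rec[0] = x0
        r0 = eff.r_eff

        def drift(yv):
            out = np.full_like(yv, r0)
            if epsilon > 0:
                out -= epsilon * np.exp(yv)
            if lam > 0:
                out += lam * np.exp(-yv)
            return out

        k = 1
        for step in range(1, n_steps + 1):
            dw = sq * rng.standard_normal(n_chains)
            f0 = drift(y)
            y_pred = y + f0 * dt + dw
            y = y + 0.5 * (f0 + drift(y_pred)) * dt + dw
            if step % record_every == 0:
                times[k] = step * dt
                rec[k] = np.exp(y)
                k += 1
    else:
        from .fitness import ou_step_factors

        alpha, beta = ou_step_factors(eff.tau_eff, eff.sigma_eff, dt)
        r = eff.r_eff + eff.sigma_eff * rng.standard_normal(n_chains)
        n = x0.copy()
        rec[0] = n
        k = 1
        for step in range(1, n_steps + 1):
            r_prev = r
            r = eff.r_eff + alpha * (r - eff.r_eff) + beta * rng.standard_normal(n_chains)
            n = n * np.exp((0.5 * (r_prev + r) - epsilon * n) * dt) + lam * dt
            if step % record_every == 0:
                times[k] = step * dt
                rec[k] = n
                k += 1
    times, rec = times[:k], rec[:k]
    if not np.all(np.isfinite(rec)):
        from .errors import IntegrationError

        bad = np.nonzero(~np.isfinite(rec).all(axis=1))[0]
        raise IntegrationError(
            f"non-finite focal abundance first recorded at t={times[bad[0]]:g}; "
            "reduce dt"
        )
    if n_chains == 1:
        return times, rec[:, 0]
    return times, rec


# ---------------------------------------------------------------------------
# maximum-likelihood GIG fit
# ---------------------------------------------------------------------------

@dataclass
class GIGFit:
    params: GIGParams
    gof: float
    loglik: float
    converged: bool
    message: str = ""


def _gig_negloglik(theta, n, log_n, inv_n):
    nu, log_a, log_b = theta
    a, b = math.exp(log_a), math.exp(log_b)
    if a <= 0 or b <= 0 or not np.isfinite(a) or not np.isfinite(b):
        return np.inf
    try:
        logc = _gig_log_norm(GIGParams(nu=nu, a=a, b=b))
    except (NormalizationError, ParameterError, ValueError, OverflowError):
        return np.inf
    # mean log-likelihood per sample: logc - nu*E[log n] - E[n]/a - b*E[1/n]
    return -(logc - nu * log_n.mean() - n.mean() / a - b * inv_n.mean())


def gof_score(samples: np.ndarray, shape: GIGParams, bins_per_decade: int = 10) -> float:
    """One minus the total-variation distance between fitted and empirical
    log-binned densities (both treated as probability masses per bin)."""
    samples = np.asarray(samples, dtype=float)
    lo, hi = np.log10(samples.min()), np.log10(samples.max())
    n_bins = max(int(np.ceil((hi - lo) * bins_per_decade)), 5)
    edges = np.logspace(lo, hi, n_bins + 1)
    emp, _ = np.histogram(samples, bins=edges)
    emp = emp / emp.sum()
    cdf = gig_cdf(edges, shape)
    fit = np.diff(cdf)
    # mass the fit places outside the sampled range counts against it
    tv = 0.5 * (np.abs(emp - fit).sum() + (1.0 - fit.sum()))
    return float(max(0.0, 1.0 - tv))


def fit_gig(samples: np.ndarray, min_samples: int = 500) -> GIGFit:
    """Maximum-likelihood fit of (nu, a, b) by direct optimization.

    Uses moment/quantile-based initial guesses with a few restarts; raises
    ``FitError`` on degenerate input or optimizer failure.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < min_samples:
        raise FitError(f"need at least {min_samples} samples, got {len(samples)}")
    if np.any(samples <= 0):
        raise FitError("samples must be strictly positive")
    if samples.std() == 0 or np.ptp(np.log(samples)) < 1e-8:
        raise FitError("degenerate (constant) samples")

    n = samples
    log_n, inv_n = np.log(n), 1.0 / n
    a0 = float(2.0 * n.mean())
    b0 = float(max(np.quantile(n, 0.05) / 2.0, 1e-12))
    starts = [(nu0, math.log(a0), math.log(b0)) for nu0 in (-0.5, 0.5, 1.0, 1.5)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _gig_negloglik, x0, args=(n, log_n, inv_n), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9},
        )
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("GIG log-likelihood optimization failed for all starts")
    nu, log_a, log_b = best.x
    params = GIGParams(nu=float(nu), a=float(math.exp(log_a)), b=float(math.exp(log_b)))
    gof = gof_score(n, params)
    if not best.success and best.fun > 1e6:
        raise FitError(f"optimizer did not converge: {best.message}")
    return GIGFit(params=params, gof=gof, loglik=float(-best.fun * len(n)),
                  converged=bool(best.success), message=str(best.message))
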