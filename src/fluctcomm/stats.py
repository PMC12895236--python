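"""Community-level summary statistics.

Effective richness, dominance time, log-binned abundance distributions
(SAD/FAD), shape indices (width W, mode n*, exponent nu), Bray-Curtis
turnover decay, and the compound Buffering / Stabilisation coordinates
B = S*lam/(K*gamma) and Sigma = K*eps/gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .community import CommunityParams, Trajectory
from .errors import ParameterError
from .focal import EffectiveParams, GIGParams, gig_shape

__all__ = [
    "effective_richness",
    "DominanceTime",
    "dominance_time",
    "LogBinnedDensity",
    "sad_histogram",
    "fad_histogram",
    "ShapeSummary",
    "shape_indices",
    "BrayCurtisDecay",
    "bray_curtis_decay",
    "buffering_stabilisation",
    "richness_trajectory",
    "richness_crossings",
]


def effective_richness(abundances: np.ndarray, axis: int = -1) -> np.ndarray:
    """Simpson's reciprocal diversity index 1/sum(p_i^2).

    Input is normalized internally, so absolute or relative abundances are
    both accepted; S_eff is invariant to abundance rescaling and lies in
    [1, S].  Raises on an all-zero composition.
    """
    n = np.asarray(abundances, dtype=float)
    tot = n.sum(axis=axis, keepdims=True)
    if np.any(tot <= 0):
        raise ParameterError("effective_richness of an all-zero composition")
    p = n / tot
    return np.squeeze(1.0 / (p**2).sum(axis=axis))


class DominanceTime(NamedTuple):
    tc: float
    censored: bool


def dominance_time(times: np.ndarray, seff: np.ndarray, threshold: float = 5.0) -> DominanceTime:
    """First time the ensemble-mean effective richness drops below a threshold.

    ``seff`` may be a single series (T,) or an ensemble (runs, T) or (T, runs)
    which is averaged over runs first.  The crossing is linearly interpolated
    between recorded times; if the mean never crosses, the result is censored
    (tc = nan).
    """
    times = np.asarray(times, dtype=float)
    s = np.asarray(seff, dtype=float)
    if s.ndim == 2:
        if s.shape[0] == len(times) and s.shape[1] != len(times):
            s = s.mean(axis=1)
        else:
            s = s.mean(axis=0)
    if s.shape != times.shape:
        raise ParameterError("seff and times are misaligned")
    below = np.nonzero(s < threshold)[0]
    if len(below) == 0:
        return DominanceTime(float("nan"), True)
    k = below[0]
    if k == 0:
        return DominanceTime(float(times[0]), False)
    t0, t1 = times[k - 1], times[k]
    s0, s1 = s[k - 1], s[k]
    tc = t0 + (s0 - threshold) / (s0 - s1) * (t1 - t0)
    return DominanceTime(float(tc), False)


@dataclass
class LogBinnedDensity:
    """Histogram on logarithmic abundance bins.

    ``density`` is normalized per decade of abundance: sum(density * width)
    over bins equals 1, with widths in log10 units.
    """

    edges: np.ndarray       # bin edges, abundance units
    density: np.ndarray     # probability density per log10(abundance)
    counts: np.ndarray
    n_total: int
    n_zero: int = 0

    @property
    def log_edges(self) -> np.ndarray:
        return np.log10(self.edges)

    @property
    def centers(self) -> np.ndarray:
        le = self.log_edges
        return 10.0 ** (0.5 * (le[:-1] + le[1:]))

    def quantile(self, q: float) -> float:
        """Abundance at cumulative probability q (interpolated in log space)."""
        w = np.diff(self.log_edges)
        cum = np.concatenate([[0.0], np.cumsum(self.density * w)])
        cum /= cum[-1]
        return float(10.0 ** np.interp(q, cum, self.log_edges))


def sad_histogram(
    abundances,
    bins_per_decade: int = 10,
    edges: Optional[np.ndarray] = None,
) -> LogBinnedDensity:
    """Log-binned species-abundance distribution.

    ``abundances`` may be a single snapshot or any collection of snapshots
    (pooling gives the time-averaged SAD).  Zeros are dropped from the
    density but counted in ``n_zero``.
    """
    if isinstance(abundances, (list, tuple)):
        n = np.concatenate([np.ravel(np.asarray(a, dtype=float)) for a in abundances])
    else:
        n = np.ravel(np.asarray(abundances, dtype=float))
    if n.size == 0:
        raise ParameterError("empty abundance input")
    n_zero = int((n <= 0).sum())
    n = n[n > 0]
    if n.size == 0:
        raise ParameterError("no positive abundances to bin")
    if edges is None:
        lo = np.floor(np.log10(n.min()) * bins_per_decade) / bins_per_decade
        hi = np.ceil(np.log10(n.max()) * bins_per_decade) / bins_per_decade
        if hi <= lo:
            hi = lo + 1.0 / bins_per_decade
        n_bins = int(round((hi - lo) * bins_per_decade))
        edges = np.logspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(n, bins=edges)
    widths = np.diff(np.log10(edges))
    total = counts.sum()
    density = counts / (total * widths)
    return LogBinnedDensity(edges=np.asarray(edges, float), density=density,
                            counts=counts, n_total=int(total), n_zero=n_zero)


def fad_histogram(
    trajectory: Trajectory,
    species_index: int,
    burn_in: float = 0.0,
    bins_per_decade: int = 10,
    edges: Optional[np.ndarray] = None,
) -> LogBinnedDensity:
    """Frequency-abundance distribution: one species' abundance across time."""
    traj = trajectory.after(burn_in)
    return sad_histogram(traj.abundance[:, species_index],
                         bins_per_decade=bins_per_decade, edges=edges)


@dataclass
class ShapeSummary:
    """SAD shape indices and Buffering-Stabilisation coordinates."""

    width_decades: float
    modal_abundance: float
    exponent: float
    method: str                       # "eq_theory" or "logfit"
    nu_logfit: Optional[float] = None
    nu_theory: Optional[float] = None
    reliable: bool = True
    B: Optional[float] = None
    Sigma: Optional[float] = None


def _logfit_exponent(density: LogBinnedDensity, lo: float, hi: float) -> Optional[float]:
    """Power-law exponent nu from the slope of log-density vs log-abundance.

    The density is per log-abundance, so P(n) ~ n^-nu appears with slope
    1 - nu; hence nu = 1 - slope.
    """
    c = density.centers
    m = (c >= lo) & (c <= hi) & (density.counts > 0)
    if m.sum() < 3:
        return None
    slope = np.polyfit(np.log10(c[m]), np.log10(density.density[m]), 1)[0]
    return float(1.0 - slope)


def shape_indices(
    density: LogBinnedDensity,
    eff: Optional[EffectiveParams] = None,
    params: Optional[CommunityParams] = None,
    min_width: float = 2.0,
) -> ShapeSummary:
    """Width W (decades, 0.5%-99.5% quantiles), modal log-bin center n*, and
    the power-law exponent nu.

    nu is reported two ways when possible: from the effective-parameter
    formula nu = 1 - 2*r_eff*/gamma_eff ("eq_theory"), and as a least-squares
    log-log slope over the mid-range [5b, a/5] when those scales are
    available and proper, else over the central 50% of W ("logfit").
    Distributions narrower than ``min_width`` decades are flagged unreliable.
    """
    q_lo, q_hi = density.quantile(0.005), density.quantile(0.995)
    W = float(np.log10(q_hi / q_lo))
    n_star = float(density.centers[np.argmax(density.density)])

    nu_theory = None
    gig: Optional[GIGParams] = None
    if eff is not None:
        nu_theory = 1.0 - 2.0 * eff.r_eff / eff.gamma_eff
        if params is not None:
            gig = gig_shape(eff, params.epsilon, params.lam)

    lo_mid = hi_mid = None
    if gig is not None and gig.b > 0 and np.isfinite(gig.a) and 5 * gig.b < gig.a / 5:
        lo_mid, hi_mid = 5.0 * gig.b, gig.a / 5.0
    else:
        half = 10.0 ** (W / 4.0)
        center = np.sqrt(q_lo * q_hi)
        lo_mid, hi_mid = center / half, center * half
    nu_logfit = _logfit_exponent(density, lo_mid, hi_mid)

    reliable = W >= min_width and nu_logfit is not None
    if nu_theory is not None:
        exponent, method = nu_theory, "eq_theory"
    elif nu_logfit is not None:
        exponent, method = nu_logfit, "logfit"
    else:
        exponent, method = float("nan"), "logfit"

    B = Sigma = None
    if params is not None:
        try:
            B, Sigma = buffering_stabilisation(params)
        except ParameterError:
            pass
    return ShapeSummary(width_decades=W, modal_abundance=n_star, exponent=exponent,
                        method=method, nu_logfit=nu_logfit, nu_theory=nu_theory,
                        reliable=reliable, B=B, Sigma=Sigma)


@dataclass
class BrayCurtisDecay:
    lags: np.ndarray
    similarity: np.ndarray
    asymptote: float


def bray_curtis_decay(
    trajectory: Trajectory,
    lags: Optional[Sequence[float]] = None,
    burn_in: float = 0.0,
    min_pairs: int = 10,
    max_lags: int = 60,
) -> BrayCurtisDecay:
    """Average Bray-Curtis similarity BC(t) between compositions a lag apart.

    BC(t) = mean over pairs (s, s+t) of sum_i min(p_i(s), p_i(s+t)) on
    relative abundances; BC(0) = 1.  The asymptote is the mean of BC over the
    largest quartile of requested lags.  Lags with fewer than ``min_pairs``
    sample pairs are dropped with a warning.
    """
    traj = trajectory.after(burn_in)
    P = traj.relative_abundance
    T = P.shape[0]
    dt = traj.dt_sample
    if lags is None:
        k_max = T - min_pairs
        ks = np.unique(np.round(np.geomspace(1, max(k_max, 1), max_lags)).astype(int))
        ks = np.concatenate([[0], ks[ks > 0]])
    else:
        ks = np.unique(np.round(np.asarray(lags, float) / dt).astype(int))
    out_lags, out_bc = [], []
    for k in ks:
        n_pairs = T - k
        if n_pairs < min_pairs and k > 0:
            warnings.warn(f"lag {k * dt:g} has only {n_pairs} pairs; dropped",
                          stacklevel=2)
            continue
        if k == 0:
            bc = 1.0
        else:
            bc = float(np.minimum(P[:-k], P[k:]).sum(axis=1).mean())
        out_lags.append(k * dt)
        out_bc.append(bc)
    out_lags = np.asarray(out_lags)
    out_bc = np.asarray(out_bc)
    if len(out_lags) == 0:
        raise ParameterError("no usable lags")
    q75 = np.quantile(out_lags, 0.75)
    tail = out_lags >= q75
    return BrayCurtisDecay(lags=out_lags, similarity=out_bc,
                           asymptote=float(out_bc[tail].mean()))


def buffering_stabilisation(params: CommunityParams):
    """Compound coordinates B = S*lam/(K*gamma), Sigma = K*eps/gamma."""
    g = params.noise.gamma
    if g is None or g <= 0:
        raise ParameterError("Buffering/Stabilisation undefined for gamma = 0")
    B = params.n_species * params.lam / (params.carrying_capacity * g)
    Sigma = params.carrying_capacity * params.epsilon / g
    return float(B), float(Sigma)


def richness_trajectory(trajectory: Trajectory, n_ext: Optional[float] = None) -> np.ndarray:
    """Count of extant species (abundance >= n_ext, or > 0 if n_ext = 0)."""
    thr = trajectory.params.n_ext if n_ext is None else n_ext
    if thr > 0:
        return (trajectory.abundance >= thr).sum(axis=1)
    return (trajectory.abundance > 0).sum(axis=1)


def richness_crossings(
    trajectory: Trajectory,
    levels: Sequence[int],
    n_ext: Optional[float] = None,
):
    """For each absolute-richness level, the first crossing time and the
    effective richness at that moment (side-panel protocol).

    Returns a list of (level, time, seff) tuples; censored levels (never
    reached) get time = nan, seff = nan.
    """
    rich = richness_trajectory(trajectory, n_ext)
    out = []
    for level in levels:
        idx = np.nonzero(rich <= level)[0]
        if len(idx) == 0:
            out.append((int(level), float("nan"), float("nan")))
        else:
            k = idx[0]
            seff = float(effective_richness(trajectory.abundance[k]))
            out.append((int(level), float(trajectory.times[k]), seff))
    return out
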