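"""Config-driven in-silico experiment protocols.

Each experiment reproduces one of the study designs of the model analysis:

- ``fig1_baseline``: single uniform-competition run, even start.
- ``fig2_scaling``: dominance-time tc vs ln S over replicate ensembles.
- ``fig3_tau``: shared-randomness runs at several tau with gamma fixed.
- ``fig4_maintenance``: richness decay vs excess self-regulation and vs
  metacommunity size/dispersal.
- ``fig5_sweep``: random parameter sweep mapped to the Buffering-
  Stabilisation plane with SAD shape indices.
- ``fig6_heterogeneity``: mean-fitness heterogeneity, per-species FADs.

Every experiment accepts ``--scale`` to shrink ensembles and horizons
deterministically, writes tidy CSVs plus a JSON manifest (parameters, seed,
runtime), and is fully reproducible from (config, seed).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import CommunityParams, simulate_community, simulate_ensemble
from .config import community_params_from_config, validate_config
from .errors import ConfigError
from .fitness import NoiseParams, draw_mean_fitnesses, standard_increments
from .focal import estimate_effective_params
from .io import save_trajectory
from .metacommunity import MetaParams, simulate_metacommunity
from .stats import (
    bray_curtis_decay,
    buffering_stabilisation,
    dominance_time,
    effective_richness,
    fad_histogram,
    richness_trajectory,
    sad_histogram,
    shape_indices,
)

__all__ = ["run_experiment", "EXPERIMENTS", "draw_sweep_parameters"]


def _scaled(value, scale, minimum=1):
    return max(minimum, int(round(value * scale)))


def _seff_reduce(n):
    p = n / n.sum(axis=1, keepdims=True)
    return 1.0 / (p**2).sum(axis=1)


def run_fig1_baseline(cfg, outdir, scale, rng_seed):
    params = community_params_from_config(cfg)
    horizon = cfg["horizon"] * scale
    traj = simulate_community(
        params, horizon=horizon, dt=cfg["dt"],
        record_every=max(1, int(round(1.0 / params.default_dt() / 2))),
        seed=rng_seed, fitness_init="mean",
    )
    save_trajectory(traj, Path(outdir) / "trajectory.tsv")
    seff = effective_richness(traj.abundance, axis=1)
    pd.DataFrame({"time": traj.times, "seff": seff,
                  "richness": richness_trajectory(traj, cfg["n_ext"] or 1e-6)}
                 ).to_csv(Path(outdir) / "richness.csv", index=False)
    return {"final_seff": float(np.atleast_1d(seff)[-1])}


def run_fig2_scaling(cfg, outdir, scale, rng_seed):
    s_grid = [25, 100, 400, 1600]
    n_runs = _scaled(200, scale, minimum=4)
    horizon = cfg["horizon"]
    rows = []
    ss = np.random.SeedSequence(rng_seed)
    for S, child in zip(s_grid, ss.spawn(len(s_grid))):
        params = community_params_from_config({**cfg, "n_species": S})
        times, seff = simulate_ensemble(
            params, n_runs, horizon=horizon, dt=cfg["dt"],
            record_every=max(1, int(round(1.0 / params.default_dt()))),
            seed=child, fitness_init="mean", reduce=_seff_reduce,
            stop_when=lambda row: row.mean() < 4.0,
        )
        tc, censored = dominance_time(times, seff.T, threshold=5.0)
        rows.append({"S": S, "ln_S": np.log(S), "tc": tc, "censored": censored,
                     "n_runs": n_runs})
    df = pd.DataFrame(rows)
    ok = df[~df["censored"]]
    slope, intercept = np.polyfit(ok["ln_S"], ok["tc"], 1)
    pred = intercept + slope * ok["ln_S"]
    ss_res = float(((ok["tc"] - pred) ** 2).sum())
    ss_tot = float(((ok["tc"] - ok["tc"].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    df.to_csv(Path(outdir) / "tc_vs_lnS.csv", index=False)
    return {"slope": float(slope), "intercept": float(intercept), "r_squared": r2}


def run_fig3_tau(cfg, outdir, scale, rng_seed):
    taus = [1.0, 10.0, 100.0]
    horizon = cfg["horizon"] * scale
    gamma = cfg["gamma"]
    finest_dt = min(min(taus), 1.0 / cfg["r_star"]) / 20.0
    n_steps = int(round(horizon / finest_dt))
    base_increments = standard_increments(n_steps + 1, cfg["n_species"], rng_seed)
    out = {}
    for tau in taus:
        params = community_params_from_config({**cfg, "tau": tau, "sigma_r": None,
                                               "gamma": gamma})
        # identical randomness across tau: same increment stream, same dt
        traj = _simulate_with_increments(params, base_increments, horizon, finest_dt)
        save_trajectory(traj, Path(outdir) / f"trajectory_tau{tau:g}.tsv",
                        fitness=False)
        out[f"tau_{tau:g}_final_seff"] = float(
            effective_richness(traj.abundance[-1]))
    return out


def _simulate_with_increments(params, increments, horizon, dt):
    """Fixed-increment integration used by the shared-randomness protocol."""
    from .community import Trajectory
    from .fitness import ou_step_factors

    S = params.n_species
    n_steps = int(round(horizon / dt))
    record_every = max(1, int(round(1.0 / dt)))
    rstar = params.noise.mean_fitness_vector(S)
    alpha, beta = ou_step_factors(params.noise.tau, params.noise.sigma_r, dt)
    mu, eps, lam, n_ext = params.mu, params.epsilon, params.lam, params.n_ext
    r = rstar.copy()
    n = params.even_init()
    rec_t, rec_n, rec_r = [0.0], [n.copy()], [r.copy()]
    for step in range(1, n_steps + 1):
        r_prev = r
        r = rstar + alpha * (r - rstar) + beta * increments[step - 1]
        N = n.sum()
        n = n * np.exp((0.5 * (r_prev + r) - mu * N - eps * n) * dt)
        if lam > 0:
            n = n + lam * dt
        if n_ext > 0:
            n[n < n_ext] = 0.0
        if step % record_every == 0:
            rec_t.append(step * dt)
            rec_n.append(n.copy())
            rec_r.append(r.copy())
    return Trajectory(np.asarray(rec_t), np.asarray(rec_n), np.asarray(rec_r),
                      params, None)


def run_fig4_maintenance(cfg, outdir, scale, rng_seed):
    horizon = cfg["horizon"] * scale
    n_runs = _scaled(20, scale, minimum=2)
    n_ext = cfg["n_ext"] or 1e-6
    mu = cfg["mu"]
    ss = np.random.SeedSequence(rng_seed)
    rows = []
    for frac, child in zip([0.0, 0.25, 0.5, 1.0], ss.spawn(4)):
        params = community_params_from_config({**cfg, "epsilon": frac * mu,
                                               "n_ext": n_ext})
        times, rich = simulate_ensemble(
            params, n_runs, horizon=horizon, dt=cfg["dt"],
            record_every=max(1, int(round(1.0 / params.default_dt()))),
            seed=child, reduce=lambda n: (n >= n_ext).sum(axis=1).astype(float),
        )
        mean_rich = rich.mean(axis=1)
        for t, rmean in zip(times[:: max(1, len(times) // 200)],
                            mean_rich[:: max(1, len(times) // 200)]):
            rows.append({"sweep": "epsilon", "value": frac * mu, "time": t,
                         "mean_richness": rmean})
    base = community_params_from_config({**cfg, "n_ext": n_ext})
    for M, child in zip([1, 2, 4], ss.spawn(3)):
        meta = MetaParams.fully_connected(M, d=cfg["dispersal"] or 0.01,
                                          base=base,
                                          coupling_mode=cfg["coupling_mode"])
        mt = simulate_metacommunity(
            meta, horizon=horizon, dt=cfg["dt"],
            record_every=max(1, int(round(1.0 / base.default_dt()))), seed=child)
        local = mt.local_richness().mean(axis=1)
        for t, rmean in zip(mt.times[:: max(1, len(mt.times) // 200)],
                            local[:: max(1, len(mt.times) // 200)]):
            rows.append({"sweep": "patches", "value": M, "time": t,
                         "mean_richness": rmean})
    pd.DataFrame(rows).to_csv(Path(outdir) / "richness_decay.csv", index=False)
    return {"n_rows": len(rows)}


def draw_sweep_parameters(n_draws: int, seed=None) -> pd.DataFrame:
    """Random base-parameter draws for the shape sweep.

    S uniform on {100..1000}; log10(gamma) in [-4, 2]; log10(tau) in [-2, 2];
    log10(eps) in [-2, 2]; log10(lam) in [-10, -4]; K = r* = 1.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "S": rng.integers(100, 1001, n_draws),
        "gamma": 10.0 ** rng.uniform(-4, 2, n_draws),
        "tau": 10.0 ** rng.uniform(-2, 2, n_draws),
        "epsilon": 10.0 ** rng.uniform(-2, 2, n_draws),
        "lam": 10.0 ** rng.uniform(-10, -4, n_draws),
        "draw_seed": rng.integers(0, 2**31 - 1, n_draws),
    })


def run_fig5_sweep(cfg, outdir, scale, rng_seed, n_draws=None):
    n_draws = n_draws if n_draws is not None else _scaled(10000, scale, minimum=4)
    draws = draw_sweep_parameters(n_draws, seed=rng_seed)
    horizon = cfg["horizon"]
    rows = []
    for rec in draws.itertuples(index=False):
        params = CommunityParams(
            n_species=int(rec.S), r_star=1.0, carrying_capacity=1.0,
            epsilon=rec.epsilon, lam=rec.lam, n_ext=0.0,
            noise=NoiseParams(mean_fitness=1.0, gamma=rec.gamma, tau=rec.tau),
        )
        record_every = max(1, int(round(min(5.0, horizon / 400) / params.default_dt())))
        traj = simulate_community(params, horizon=horizon, dt=params.default_dt(),
                                  record_every=record_every, seed=int(rec.draw_seed))
        burn = 0.5 * horizon
        stat = traj.after(burn)
        density = sad_histogram(stat.abundance)
        try:
            eff = estimate_effective_params(traj, burn_in_frac=0.5)
        except Exception:
            eff = None
        summ = shape_indices(density, eff=eff, params=params)
        B, Sigma = buffering_stabilisation(params)
        rows.append({
            "S": rec.S, "gamma": rec.gamma, "tau": rec.tau,
            "epsilon": rec.epsilon, "lam": rec.lam, "seed": rec.draw_seed,
            "B": B, "Sigma": Sigma, "W": summ.width_decades,
            "n_star": summ.modal_abundance, "nu": summ.exponent,
            "nu_logfit": summ.nu_logfit, "reliable": summ.reliable,
        })
    df = pd.DataFrame(rows)
    df.to_csv(Path(outdir) / "shape_sweep.csv", index=False)
    return {"n_draws": int(n_draws)}


REGIME_SETS = {
    "Ex": {"epsilon": 0.05, "lam": 1e-8},
    "BuSt": {"epsilon": 50.0, "lam": 3.2e-5},
}


def run_fig6_heterogeneity(cfg, outdir, scale, rng_seed):
    horizon = cfg["horizon"] * scale
    S = cfg["n_species"]
    ss = np.random.SeedSequence(rng_seed)
    children = iter(ss.spawn(2 * 3))
    rows = []
    for regime, extra in REGIME_SETS.items():
        for ratio in [0.0, 2.0, 10.0]:
            child = next(children)
            sigma_r = (cfg["gamma"] / (2 * cfg["tau"])) ** 0.5
            delta = ratio * sigma_r
            means = draw_mean_fitnesses(cfg["r_star"], min(delta, cfg["r_star"]),
                                        S, seed=child)
            params = CommunityParams(
                n_species=S, r_star=cfg["r_star"],
                carrying_capacity=cfg["carrying_capacity"],
                epsilon=extra["epsilon"], lam=extra["lam"], n_ext=0.0,
                noise=NoiseParams(mean_fitness=means, gamma=cfg["gamma"],
                                  tau=cfg["tau"]),
            )
            record_every = max(1, int(round(5.0 / params.default_dt())))
            traj = simulate_community(params, horizon=horizon,
                                      record_every=record_every, seed=child)
            burn = 0.2 * horizon
            order = np.argsort(means)
            for label, j in [("low", order[0]), ("mid", order[S // 2]),
                             ("high", order[-1])]:
                fad = fad_histogram(traj, j, burn_in=burn)
                rows.append({
                    "regime": regime, "delta_over_sigma": ratio,
                    "species": label, "r_star_i": means[j],
                    "median_abundance": fad.quantile(0.5),
                })
            bc = bray_curtis_decay(traj, burn_in=burn)
            rows.append({"regime": regime, "delta_over_sigma": ratio,
                         "species": "BC_asymptote", "r_star_i": np.nan,
                         "median_abundance": bc.asymptote})
    pd.DataFrame(rows).to_csv(Path(outdir) / "heterogeneity.csv", index=False)
    return {"n_rows": len(rows)}


DEFAULT_HORIZONS = {
    "fig1_baseline": 5000.0,
    "fig2_scaling": 2500.0,
    "fig3_tau": 2000.0,
    "fig4_maintenance": 5000.0,
    "fig5_sweep": 2000.0,
    "fig6_heterogeneity": 500_000.0,
}

EXPERIMENTS = {
    "fig1_baseline": run_fig1_baseline,
    "fig2_scaling": run_fig2_scaling,
    "fig3_tau": run_fig3_tau,
    "fig4_maintenance": run_fig4_maintenance,
    "fig5_sweep": run_fig5_sweep,
    "fig6_heterogeneity": run_fig6_heterogeneity,
}


def run_experiment(name: str, config=None, outdir=".", scale: float = 1.0,
                   seed=None, **kwargs) -> dict:
    """Run a named experiment protocol and write results + manifest to outdir."""
    if name not in EXPERIMENTS:
        raise ConfigError([f"unknown experiment {name!r}; choose from "
                           f"{sorted(EXPERIMENTS)}"])
    from .config import load_config

    raw = load_config(config)
    cfg = validate_config(config)
    if "horizon" not in raw:
        cfg["horizon"] = DEFAULT_HORIZONS[name]
    if name == "fig6_heterogeneity" and "n_species" not in raw:
        cfg["n_species"] = 500
    if seed is None:
        seed = cfg["seed"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    summary = EXPERIMENTS[name](cfg, outdir, scale, seed, **kwargs)
    runtime = time.perf_counter() - t0
    manifest = {
        "experiment": name,
        "config": {k: v for k, v in cfg.items()},
        "scale": scale,
        "seed": int(seed) if np.isscalar(seed) else str(seed),
        "version": __version__,
        "runtime_s": round(runtime, 3),
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=float))
    return manifest
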