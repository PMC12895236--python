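import numpy as np
import pytest

from fluctcomm import (
    CommunityParams,
    NoiseParams,
    focal_delta_r,
    integrated_fitness,
    replicator_solution,
    simulate_community,
    simulate_ensemble,
)
from fluctcomm.errors import ParameterError
from fluctcomm.stats import dominance_time, effective_richness

from conftest import seff_reduce


def noiseless(n_species, epsilon=0.0, lam=0.0, n_ext=0.0):
    return CommunityParams(
        n_species=n_species, epsilon=epsilon, lam=lam, n_ext=n_ext,
        noise=NoiseParams(mean_fitness=1.0, sigma_r=0.0, tau=10.0),
    )


class TestDeterministicLimits:
    def test_total_abundance_equilibrates_at_K(self):
        params = noiseless(10)
        traj = simulate_community(params, init=np.full(10, 0.01), horizon=60.0,
                                  record_every=10, seed=0)
        N = traj.total_abundance
        assert N[-1] == pytest.approx(params.carrying_capacity, rel=1e-6)
        # and stays there
        assert np.all(np.abs(N[len(N) // 2:] - 1.0) < 1e-3)

    def test_even_community_is_fixed_point(self):
        params = noiseless(5)
        traj = simulate_community(params, horizon=30.0, seed=0)
        assert np.allclose(traj.abundance[-1], params.even_init(), rtol=1e-9)

    def test_single_species_logistic_fixed_point(self):
        eps = 0.5
        params = noiseless(1, epsilon=eps)
        traj = simulate_community(params, init=np.array([0.1]), horizon=80.0,
                                  seed=0)
        expected = params.r_star / (params.mu + eps)
        assert traj.abundance[-1, 0] == pytest.approx(expected, rel=1e-6)

    def test_abundances_never_negative(self, small_community):
        traj = simulate_community(small_community, horizon=200.0,
                                  record_every=5, seed=8)
        assert np.all(traj.abundance >= 0)

    def test_invalid_init_shape(self, small_community):
        with pytest.raises(ParameterError):
            simulate_community(small_community, init=np.ones(3), horizon=1.0)

    def test_negative_init_rejected(self, small_community):
        with pytest.raises(ParameterError):
            simulate_community(small_community, init=-np.ones(20), horizon=1.0)

    def test_dt_above_tau_warns(self):
        params = CommunityParams(n_species=3, noise=NoiseParams(gamma=0.05, tau=0.5))
        with pytest.warns(UserWarning, match="under-resolved"):
            simulate_community(params, horizon=5.0, dt=1.0, seed=0)


class TestExtinctionCutoff:
    def test_cutoff_zeroes_small_abundances(self):
        params = CommunityParams(n_species=30, n_ext=1e-3,
                                 noise=NoiseParams(gamma=0.05, tau=10.0))
        traj = simulate_community(params, horizon=500.0, record_every=50, seed=4)
        final = traj.abundance[-1]
        assert np.all((final == 0) | (final >= 1e-3 * 1e-3))

    def test_init_below_cutoff_is_zeroed(self):
        params = CommunityParams(n_species=4, n_ext=0.2,
                                 noise=NoiseParams(mean_fitness=1.0, sigma_r=0.0,
                                                   tau=10.0))
        traj = simulate_community(params, init=np.full(4, 0.1), horizon=5.0,
                                  seed=0)
        assert np.all(traj.abundance == 0.0)

    def test_immigration_reseeds_after_cutoff(self):
        # cutoff keeps +lam unconditionally, so an empty community is
        # re-seeded whenever lam*dt clears the threshold
        params = CommunityParams(n_species=4, lam=0.05, n_ext=0.002,
                                 noise=NoiseParams(mean_fitness=1.0, sigma_r=0.0,
                                                   tau=10.0))
        traj = simulate_community(params, init=np.zeros(4), horizon=100.0,
                                  dt=0.05, record_every=20, seed=0)
        assert traj.abundance[0].sum() == 0.0
        assert traj.total_abundance[-1] > 0.9 * params.carrying_capacity


class TestReplicator:
    def test_identical_fitness_keeps_composition(self):
        times = np.linspace(0, 10, 101)
        r = np.ones((101, 4)) * np.sin(times)[:, None]  # same path for all
        p0 = np.array([0.1, 0.2, 0.3, 0.4])
        P = replicator_solution(r, times, p0)
        assert np.allclose(P, p0[None, :], atol=1e-12)

    def test_two_species_logistic_closed_form(self):
        delta = 0.3
        times = np.linspace(0, 20, 201)
        r = np.column_stack([np.full(201, delta), np.zeros(201)])
        p0 = np.array([0.2, 0.8])
        P = replicator_solution(r, times, p0)
        # oracle: p1(t) = p1(0) e^{dt} / (p1(0) e^{dt} + p2(0))
        expected = p0[0] * np.exp(delta * times) / (
            p0[0] * np.exp(delta * times) + p0[1])
        assert np.allclose(P[:, 0], expected, atol=1e-10)

    def test_rows_sum_to_one_even_with_extreme_fitness(self):
        times = np.linspace(0, 100, 51)
        rng = np.random.default_rng(0)
        r = rng.normal(0, 20, (51, 6))
        P = replicator_solution(r, times, np.full(6, 1 / 6))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_off_simplex_p0_rejected(self):
        with pytest.raises(ParameterError):
            replicator_solution(np.zeros((3, 2)), np.arange(3.0),
                                np.array([0.7, 0.7]))

    def test_simulation_matches_replicator_oracle(self, baseline_noise):
        params = CommunityParams(n_species=30, noise=baseline_noise)
        traj = simulate_community(params, horizon=100.0, dt=0.05, seed=5,
                                  fitness_init="mean")
        P_oracle = replicator_solution(traj.fitness, traj.times,
                                       np.full(30, 1 / 30))
        err = np.max(np.abs(traj.relative_abundance - P_oracle))
        assert err < 1e-3

    def test_composition_exact_for_uniform_competition(self, baseline_noise):
        # with midpoint fitness the split scheme reproduces the replicator
        # solution on the same fitness grid to machine precision at any dt
        params = CommunityParams(n_species=10, noise=baseline_noise)
        for dt in (0.2, 0.05):
            traj = simulate_community(params, horizon=50.0, dt=dt, seed=9,
                                      fitness_init="mean")
            P = replicator_solution(traj.fitness, traj.times, np.full(10, 0.1))
            assert np.max(np.abs(traj.relative_abundance - P)) < 1e-12

    def test_convergence_order_in_dt_full_dynamics(self):
        # order >= 1 against a tight ODE reference, probed where splitting
        # error actually appears (self-regulation + immigration)
        from scipy.integrate import solve_ivp

        from fluctcomm.fitness import periodic_fitness

        S = 5
        phases = np.linspace(0.3, 5.9, S)
        noise = NoiseParams(mean_fitness=1.0, sigma_r=0.2, tau=2.0,
                            mode="periodic", phases=phases)
        params = CommunityParams(n_species=S, epsilon=0.4, lam=0.01, noise=noise)
        amp = np.sqrt(2) * 0.2

        def rhs(t, n):
            r = 1.0 + amp * np.cos(t / 2.0 - phases)
            return n * (r - params.mu * n.sum() - params.epsilon * n) + params.lam

        n0 = params.even_init()
        ref = solve_ivp(rhs, (0, 20.0), n0, rtol=1e-11, atol=1e-13,
                        t_eval=[20.0]).y[:, -1]
        errs = []
        for dt in (0.2, 0.1, 0.05):
            traj = simulate_community(params, horizon=20.0, dt=dt,
                                      record_every=int(round(20.0 / dt)), seed=0)
            errs.append(np.max(np.abs(traj.abundance[-1] - ref)))
        order = np.log2(errs[0] / errs[2]) / 2
        assert errs[2] < errs[1] < errs[0]
        assert order >= 0.8  # approaches 1 from below as dt -> 0

    def test_total_abundance_closure(self, baseline_noise):
        # dN/dt = N(rho - mu N) under uniform competition, no immigration
        params = CommunityParams(n_species=15, noise=baseline_noise)
        traj = simulate_community(params, horizon=50.0, dt=0.02, seed=2)
        N = traj.total_abundance
        rho = (traj.fitness * traj.relative_abundance).sum(axis=1)
        dN = np.gradient(N, traj.times)
        rhs = N * (rho - params.mu * N)
        mask = slice(5, -5)
        assert np.allclose(dN[mask], rhs[mask], atol=5e-3)


class TestFocalDeltaR:
    def test_two_species_is_fitness_difference(self, baseline_noise):
        params = CommunityParams(n_species=2, noise=baseline_noise)
        traj = simulate_community(params, horizon=50.0, seed=3)
        dr = focal_delta_r(traj, 0)
        assert np.allclose(dr, traj.fitness[:, 0] - traj.fitness[:, 1])

    def test_equal_fitness_gives_zero(self):
        params = noiseless(5)
        traj = simulate_community(params, horizon=10.0, seed=0)
        assert np.allclose(focal_delta_r(traj, 2), 0.0, atol=1e-12)

    def test_out_of_range_focal(self, small_community):
        traj = simulate_community(small_community, horizon=5.0, seed=0)
        with pytest.raises(ParameterError):
            focal_delta_r(traj, 20)

    def test_drives_logistic_replicator_flow(self, baseline_noise):
        # dp1/dt ~ delta_r * p1 * (1 - p1) pointwise along the trajectory
        params = CommunityParams(n_species=8, noise=baseline_noise)
        traj = simulate_community(params, horizon=80.0, dt=0.02, seed=6,
                                  fitness_init="mean")
        p1 = traj.relative_abundance[:, 0]
        dr = focal_delta_r(traj, 0)
        dp = np.gradient(p1, traj.times)
        rhs = dr * p1 * (1 - p1)
        resid = np.abs(dp - rhs)[5:-5]
        assert np.quantile(resid, 0.95) < 5e-3


class TestIntegratedFitness:
    def test_constant_fitness_linear(self):
        times = np.linspace(0, 10, 11)
        r = np.full((11, 3), 2.0)
        R = integrated_fitness(r, times)
        assert np.allclose(R, 2.0 * times[:, None])

    def test_variance_growth_slope_gamma(self, baseline_noise):
        # cross-species Var[R_i(t=200)] ~ gamma * t = 10 for gamma=0.05
        from fluctcomm.fitness import sample_fitness_paths

        times = np.arange(0.0, 200.0, 0.5)
        r = sample_fitness_paths(baseline_noise, 3000, times, seed=11)
        R = integrated_fitness(r, times)
        tau = baseline_noise.tau
        expected = 0.05 * (200.0 - tau * (1 - np.exp(-200.0 / tau)))
        assert R[-1].var() == pytest.approx(expected, rel=0.15)

    def test_periodic_variance_bounded(self):
        from fluctcomm.fitness import periodic_fitness

        p = NoiseParams(mean_fitness=1.0, sigma_r=0.3, tau=5.0, mode="periodic")
        times = np.arange(0.0, 2000.0, 0.5)
        r = periodic_fitness(p, 50, times, seed=1)
        R = integrated_fitness(r, times)
        spread = R.var(axis=1)
        bound = (2 * np.sqrt(2) * 0.3 * 5.0) ** 2  # max possible amplitude^2
        assert spread.max() < bound


class TestEnsembleAndDominance:
    def test_ensemble_shapes_and_reduce(self, small_community):
        times, seff = simulate_ensemble(small_community, 4, horizon=20.0,
                                        record_every=10, seed=1,
                                        reduce=seff_reduce)
        assert seff.shape == (len(times), 4)
        assert np.all(seff <= 20.0 + 1e-9) and np.all(seff >= 1.0)

    def test_doubling_gamma_halves_dominance_time(self):
        # tc ~ 1/gamma (Monte-Carlo tolerance)
        tcs = {}
        for gamma in (0.05, 0.1):
            params = CommunityParams(
                n_species=50, noise=NoiseParams(gamma=gamma, tau=10.0))
            times, seff = simulate_ensemble(
                params, 30, horizon=1200.0, record_every=20, seed=17,
                fitness_init="mean", reduce=seff_reduce,
                stop_when=lambda row: row.mean() < 4.0)
            tcs[gamma] = dominance_time(times, seff.T, threshold=5.0).tc
        ratio = tcs[0.05] / tcs[0.1]
        assert 1.5 < ratio < 2.6

    def test_periodic_fitness_no_monodominance(self):
        params = CommunityParams(
            n_species=30,
            noise=NoiseParams(mean_fitness=1.0, gamma=0.05, tau=10.0,
                              mode="periodic"))
        times, seff = simulate_ensemble(params, 2, horizon=2000.0,
                                        record_every=50, seed=23,
                                        reduce=seff_reduce)
        assert seff.min() > 2.0
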