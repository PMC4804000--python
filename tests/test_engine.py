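"""Stochastic engine: uncertainty model, truncation rules, reproducibility."""

import numpy as np
import pytest
from scipy.stats import norm

from polarpva.engine import (
    HarvestInterval,
    HarvestSchedule,
    RateSampler,
    SimulationConfig,
    allocate_initial_state,
    simulate_ensemble,
    simulate_run,
)
from polarpva.lifecycle import (
    AgeSexDistribution,
    PopulationState,
    deterministic_project,
    stable_age_distribution,
)
from polarpva.rates import Rate, VitalRates, uniform_survival


class TestRateSampler:
    def test_zero_se_realizes_means_exactly(self, toy_rates, rng):
        sampler = RateSampler(toy_rates, SimulationConfig(seed=0))
        sampler.draw_run(rng)
        vals = sampler.draw_year(rng)
        np.testing.assert_array_equal(vals, sampler.means)
        assert sampler.clip_events == 0

    def test_r1_shares_one_deviate_across_parameters(self, rng):
        rates = VitalRates(
            "X",
            uniform_survival(0.5, 0.05),
            litter_production={10: Rate(0.5, 0.05)},
        )
        cfg = SimulationConfig(correlation_mode="R1", seed=0)
        sampler = RateSampler(rates, cfg)
        draws = []
        for _ in range(10_000):
            sampler.draw_run(rng)
            draws.append(sampler.draw_year(rng))
        draws = np.array(draws)
        corr = np.corrcoef(draws[:, 0], draws[:, 8])  # a survival vs the LPR
        assert corr[0, 1] > 0.99

    def test_run_level_component_sd_matches_partition(self, rng):
        # param_fraction 0.75, se 0.04: run-level SD should be sqrt(.75)*.04
        rates = VitalRates("X", uniform_survival(0.5, 0.04), litter_production={})
        cfg = SimulationConfig(param_fraction=0.75, env_fraction=0.25, seed=0)
        sampler = RateSampler(rates, cfg)
        n = 10_000
        comp = np.empty(n)
        for i in range(n):
            sampler.draw_run(rng)
            comp[i] = sampler._run_offset[0]
        expected = np.sqrt(0.75) * 0.04
        mc_se = expected / np.sqrt(2 * n)  # SE of a sample SD
        assert abs(comp.std(ddof=1) - expected) < 3 * mc_se

    def test_clipping_is_tallied(self, rng):
        rates = VitalRates("X", uniform_survival(0.98, 0.2), litter_production={})
        sampler = RateSampler(rates, SimulationConfig(seed=0))
        for _ in range(200):
            sampler.draw_run(rng)
            vals = sampler.draw_year(rng)
            surv = vals[:8]  # probability parameters clip to [0, 1]
            assert (surv <= 1.0).all() and (surv >= 0.0).all()
        assert sampler.clip_events > 0


class TestConfigValidation:
    def test_partition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(param_fraction=0.75, env_fraction=0.75)

    def test_overlapping_harvest_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            HarvestSchedule(
                [HarvestInterval(1997, 2003, 10), HarvestInterval(2002, 2013, 5)]
            )

    def test_schedule_lookup_and_gaps(self):
        sched = HarvestSchedule(
            [HarvestInterval(2000, 2005, 12, 0.4), HarvestInterval(2008, 2010, 3, 0.2)]
        )
        assert sched.removals_at(2004) == (12, 0.4)
        assert sched.removals_at(2006) == (0.0, 0.0)
        assert sched.removals_at(2008) == (3, 0.2)


class TestSimulateRun:
    def test_constant_population_without_demography(self):
        rates = VitalRates("X", uniform_survival(1.0), litter_production={})
        sad = stable_age_distribution(rates)
        rng = np.random.default_rng(0)
        run = simulate_run(
            rates, (500, 0), sad, HarvestSchedule.none(),
            SimulationConfig(horizon=10, seed=0), rng,
        )
        assert not run.truncated
        np.testing.assert_array_equal(run.trajectory, 500)

    def test_initial_deviate_truncation_fraction(self, toy_rates, toy_sad):
        # fraction of nonpositive initial draws should match Phi(-N/SE)
        n_hat, se, n_runs = 100.0, 80.0, 2000
        cfg = SimulationConfig(n_iterations=n_runs, horizon=1, seed=11)
        ens = simulate_ensemble(toy_rates, (n_hat, se), toy_sad, HarvestSchedule.none(), cfg)
        frac = sum(r.truncation_cause == "initial_deviate" for r in ens.runs) / n_runs
        p = norm.cdf(-n_hat / se)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n_runs)

    def test_truncated_run_is_zero_onward(self, toy_rates, toy_sad):
        sched = HarvestSchedule.constant(150, 0.4)
        cfg = SimulationConfig(n_iterations=30, horizon=20, seed=5)
        ens = simulate_ensemble(toy_rates, (200, 0), toy_sad, sched, cfg)
        assert ens.truncation_proportion == 1.0
        for run in ens.runs:
            assert run.truncation_cause == "harvest_infeasible"
            assert (run.trajectory[run.truncation_year:] == 0).all()
            assert (run.trajectory >= 0).all()

    def test_single_sex_population_cannot_fill_female_quota(self):
        rates = VitalRates("X", uniform_survival(1.0), litter_production={})
        dist_state = PopulationState.empty(31)
        dist_state.males[10] = 1.0
        dist = AgeSexDistribution(dist_state)
        rng = np.random.default_rng(1)
        run = simulate_run(
            rates, (300, 0), dist, HarvestSchedule.constant(10, 1.0),
            SimulationConfig(horizon=5, seed=0), rng,
        )
        assert run.truncated and run.truncation_cause == "harvest_infeasible"

    def test_extinction_truncation(self):
        rates = VitalRates("X", uniform_survival(0.05), litter_production={})
        sad_state = PopulationState.empty(31)
        sad_state.f_avail[10] = 1.0
        rng = np.random.default_rng(2)
        run = simulate_run(
            rates, (20, 0), AgeSexDistribution(sad_state), HarvestSchedule.none(),
            SimulationConfig(horizon=20, seed=0), rng,
        )
        assert run.truncated and run.truncation_cause == "extinction"


class TestEnsemble:
    def test_single_iteration_wraps_one_run(self, toy_rates, toy_sad):
        cfg = SimulationConfig(n_iterations=1, horizon=3, seed=0)
        ens = simulate_ensemble(toy_rates, (100, 0), toy_sad, HarvestSchedule.none(), cfg)
        assert ens.n_runs == 1
        assert ens.trajectories.shape == (1, 4)

    def test_identical_seed_bitwise_identical(self, uncertain_rates, uncertain_sad):
        cfg = SimulationConfig(n_iterations=20, horizon=10, seed=77)
        a = simulate_ensemble(uncertain_rates, (800, 100), uncertain_sad,
                              HarvestSchedule.constant(8, 0.4), cfg)
        b = simulate_ensemble(uncertain_rates, (800, 100), uncertain_sad,
                              HarvestSchedule.constant(8, 0.4), cfg)
        np.testing.assert_array_equal(a.trajectories, b.trajectories)
        c = simulate_ensemble(
            uncertain_rates, (800, 100), uncertain_sad,
            HarvestSchedule.constant(8, 0.4),
            SimulationConfig(n_iterations=20, horizon=10, seed=78),
        )
        assert not np.array_equal(a.trajectories, c.trajectories)

    def test_zero_variance_mean_matches_deterministic(self, toy_rates, toy_sad):
        n0 = 5000
        cfg = SimulationConfig(n_iterations=150, horizon=15, seed=3)
        ens = simulate_ensemble(toy_rates, (n0, 0), toy_sad, HarvestSchedule.none(), cfg)
        init = PopulationState(
            toy_sad.state.f_avail * n0,
            toy_sad.state.males * n0,
            toy_sad.state.mothers * n0,
        )
        det = deterministic_project(toy_rates, init, 15)
        mean = ens.trajectories.mean(axis=0)
        se = ens.trajectories.std(axis=0, ddof=1) / np.sqrt(ens.n_runs)
        # demographic noise only: ensemble mean within 3 SE of expectation
        assert (np.abs(mean[1:] - det[1:]) < 3 * se[1:] + 1e-9).all()

    def test_final_state_bookkeeping_consistent(self, uncertain_rates, uncertain_sad):
        cfg = SimulationConfig(n_iterations=5, horizon=10, seed=9,
                               record_final_state=True)
        ens = simulate_ensemble(uncertain_rates, (2000, 0), uncertain_sad,
                                HarvestSchedule.constant(30, 0.35), cfg)
        for run in ens.runs:
            if run.final_state is not None:
                run.final_state.validate()
                assert int(run.final_state.total()) == run.trajectory[-1]


class TestInitialAllocation:
    def test_allocation_hits_exact_total(self, toy_sad, rng):
        for n in (1, 17, 500, 10_000):
            state = allocate_initial_state(n, toy_sad, rng)
            assert int(state.total()) == n
            state.validate()
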