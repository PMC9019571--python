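"""Exploration workflow: samplers, optimizers on benchmark oracles,
effective-set characterization, ranking and robustness plumbing."""

import numpy as np
import pytest

import tumorpulse as tp
from tumorpulse.explore import (CMAParams, ExplorationRecord, GAParams,
                                SearchSpace, characterize_effective,
                                cmaes_minimize, cmaes_optimize, ga_minimize,
                                ga_optimize, rank_by_total_tnf,
                                records_dataframe, robustness_analysis,
                                sample_candidates, sweep)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

BOX3 = [(-1.0, 1.0)] * 3


def sphere(x):
    return float(np.sum(x ** 2))


def rosenbrock(x):
    return float(np.sum(100 * (x[1:] - x[:-1] ** 2) ** 2
                        + (1 - x[:-1]) ** 2))


# deterministic synthetic treatment-response surface with a known minimizer
SURFACE_OPT = np.array([300.0, 60.0, 0.4])


def treatment_surface(x):
    space = SearchSpace()
    z = (np.asarray(x) - space.lower) / (space.upper - space.lower)
    z0 = (SURFACE_OPT - space.lower) / (space.upper - space.lower)
    return float(np.sum((z - z0) ** 2) + 0.3 * np.sum((z - z0) ** 2) ** 2)


def make_record(period, duration, conc, fitness=0.0, effective=True,
                ttnf=None):
    sched = tp.PulseSchedule(period, duration, conc)
    return ExplorationRecord(
        schedule=sched, finals=[int(fitness)] * 3, fitness=fitness,
        effective=effective,
        total_tnf=tp.total_tnf(sched, 4640.0) if ttnf is None else ttnf,
        algorithm="test", iteration=0, seed=0)


class TestSampling:
    def test_zero_candidates(self):
        assert sample_candidates(SearchSpace(), 0, "uniform", 0).shape == \
            (0, 3)

    def test_candidates_within_bounds(self):
        space = SearchSpace()
        pts = sample_candidates(space, 500, "uniform", 3)
        assert np.all(pts >= space.lower) and np.all(pts <= space.upper)
        grid = sample_candidates(space, 27, "grid", 0)
        assert np.all(grid >= space.lower) and np.all(grid <= space.upper)

    def test_same_seed_same_candidates(self):
        a = sample_candidates(SearchSpace(), 50, "uniform", 9)
        b = sample_candidates(SearchSpace(), 50, "uniform", 9)
        assert np.array_equal(a, b)


class TestSweep:
    @pytest.fixture(scope="class")
    def tiny_cfg(self, fast_steps):
        return tp.SimulationConfig(steps=fast_steps, horizon=60.0,
                                   radius=20.0, seeds=(0, 1))

    def test_records_complete_and_bounded(self, tiny_cfg):
        recs = sweep(SearchSpace(), 4, "uniform", tiny_cfg, seed=1)
        assert len(recs) == 4
        df = records_dataframe(recs)
        space = SearchSpace()
        for i, p in enumerate(("period", "duration", "concentration")):
            assert df[p].between(*space.bounds[i]).all()
        for r in recs:
            assert r.fitness == pytest.approx(np.mean(r.finals))

    def test_sweep_deterministic(self, tiny_cfg):
        a = sweep(SearchSpace(), 3, "uniform", tiny_cfg, seed=5)
        b = sweep(SearchSpace(), 3, "uniform", tiny_cfg, seed=5)
        assert [r.finals for r in a] == [r.finals for r in b]

    def test_empty_sweep(self, tiny_cfg):
        assert sweep(SearchSpace(), 0, "uniform", tiny_cfg, seed=0) == []

    def test_parallel_equals_serial(self, tiny_cfg):
        a = sweep(SearchSpace(), 4, "uniform", tiny_cfg, seed=5)
        b = sweep(SearchSpace(), 4, "uniform", tiny_cfg, seed=5, workers=2)
        assert [r.finals for r in a] == [r.finals for r in b]
        assert [r.schedule for r in a] == [r.schedule for r in b]


class TestTreatmentOptimizers:
    """The simulation-backed wrappers around the optimizer cores."""

    @pytest.fixture(scope="class")
    def tiny_cfg(self, fast_steps):
        return tp.SimulationConfig(steps=fast_steps, horizon=60.0,
                                   radius=20.0, seeds=(0,))

    def test_ga_optimize_records_respect_bounds(self, tiny_cfg):
        records, best, history = ga_optimize(
            SearchSpace(), tiny_cfg,
            GAParams(pop_size=6, generations=2), seed=0)
        space = SearchSpace()
        df = records_dataframe(records)
        for i, p in enumerate(("period", "duration", "concentration")):
            assert df[p].between(*space.bounds[i]).all()
        assert best.fitness == min(r.fitness for r in records)
        assert len(history) == 2

    def test_cmaes_optimize_reports_distribution(self, tiny_cfg):
        records, best, result = cmaes_optimize(
            SearchSpace(), tiny_cfg, CMAParams(lam=4, iterations=2), seed=0)
        space = SearchSpace()
        assert np.all(result.mean >= space.lower)
        assert np.all(result.mean <= space.upper)
        assert best.fitness == min(r.fitness for r in records)


class TestGA:
    def test_sphere_benchmark_all_seeds(self):
        for seed in range(10):
            _, best_f, hist = ga_minimize(BOX3, sphere,
                                          GAParams(generations=50), seed)
            assert best_f < 1e-3
            bests = [h[1] for h in hist]
            assert all(b2 <= b1 + 1e-12
                       for b1, b2 in zip(bests, bests[1:])), \
                "elitism keeps best fitness non-increasing"

    def test_recovers_synthetic_surface_minimizer(self):
        space = SearchSpace()
        best_x, best_f, _ = ga_minimize(space.bounds, treatment_surface,
                                        GAParams(generations=60), seed=2)
        rel = np.abs(best_x - SURFACE_OPT) / (space.upper - space.lower)
        assert np.all(rel < 0.05)

    def test_pop_size_validated(self):
        with pytest.raises(ValueError):
            ga_minimize(BOX3, sphere, GAParams(pop_size=1), 0)


class TestCMAES:
    def test_sphere_to_1e6_within_200_evals(self):
        r = cmaes_minimize(BOX3, sphere,
                           CMAParams(lam=6, sigma0=0.05, iterations=40,
                                     ftol=1e-6), seed=1)
        assert r.best_f < 1e-6
        assert r.evaluations <= 200

    def test_rosenbrock_to_1e3_within_2000_evals(self):
        r = cmaes_minimize([(-2.0, 2.0)] * 3, rosenbrock,
                           CMAParams(lam=12, iterations=166, ftol=1e-3),
                           seed=0)
        assert r.best_f < 1e-3
        assert r.evaluations <= 2000

    def test_synthetic_surface_minimizer_and_contraction(self):
        space = SearchSpace()
        r = cmaes_minimize(space.bounds, treatment_surface,
                           CMAParams(lam=12, iterations=80), seed=3)
        rel = np.abs(r.best_x - SURFACE_OPT) / (space.upper - space.lower)
        assert np.all(rel < 0.05)
        # the final sampling distribution is tight on every (normalised) axis
        axis_sd = r.sigma * np.sqrt(np.diag(r.cov))
        assert np.all(axis_sd < 0.10)

    def test_reports_distribution(self):
        r = cmaes_minimize(BOX3, sphere, CMAParams(lam=8, iterations=10),
                           seed=0)
        assert r.mean.shape == (3,) and r.cov.shape == (3, 3)
        assert r.sigma > 0


class TestCharacterization:
    def test_single_record_stats_degenerate(self):
        stats, corr = characterize_effective([make_record(400, 50, 0.5)])
        row = stats.loc["period"]
        assert row["mean"] == row["median"] == row["min"] == row["max"] == 400

    def test_duplicated_records_zero_sd(self):
        recs = [make_record(400, 50, 0.5) for _ in range(5)]
        stats, _ = characterize_effective(recs)
        assert np.allclose(stats["std"].fillna(0), 0.0)

    def test_constructed_perfect_correlation(self):
        recs = [make_record(2.0 * d, d, 0.1 + 0.001 * d)
                for d in (10, 20, 40, 80)]
        _, corr = characterize_effective(recs)
        row = corr[(corr.param_a == "period") & (corr.param_b == "duration")]
        assert row["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_empty_effective_set_warns(self):
        with pytest.warns(UserWarning, match="no effective"):
            stats, corr = characterize_effective(
                [make_record(400, 50, 0.5, effective=False)])
        assert stats.empty and corr.empty


class TestRanking:
    def test_orders_by_total_tnf(self):
        lo = make_record(464, 10, 0.5)        # total 50
        hi = make_record(46.4, 10, 0.5)       # total 500
        assert rank_by_total_tnf([hi, lo])[0] is lo

    def test_excludes_non_effective_and_handles_empty(self):
        bad = make_record(400, 50, 0.5, effective=False)
        assert rank_by_total_tnf([bad]) == []
        assert rank_by_total_tnf([]) == []

    def test_ties_broken_by_fitness(self):
        a = make_record(464, 10, 0.5, fitness=3.0)
        b = make_record(464, 10, 0.5, fitness=1.0)
        assert rank_by_total_tnf([a, b])[0] is b


class TestTopSelection:
    def test_prefers_full_eradication(self):
        erad = make_record(400, 20, 0.3, fitness=0.0)
        erad.finals = [0, 0, 0]
        near = make_record(300, 20, 0.3, fitness=0.7)
        near.finals = [1, 1, 0]
        from tumorpulse.explore import select_top_treatments
        assert select_top_treatments([near, erad], k=30) == [erad]
        # without full eradication the effective set is used
        assert select_top_treatments([near], k=30) == [near]
        assert select_top_treatments(
            [near, erad], k=30, require_eradication=False) == [erad, near]


class TestRobustness:
    def test_sigma_zero_reproduces_baseline(self, fast_steps):
        cfg = tp.SimulationConfig(steps=fast_steps, horizon=120.0,
                                  radius=20.0)
        sched = tp.PulseSchedule(150, 20, 0.3)
        from tumorpulse.simulation import score_treatment
        _, base_finals = score_treatment(cfg, sched, seeds=[7, 8])
        rec = make_record(*sched.as_tuple())
        table = robustness_analysis([rec], [0.0, 0.5], cfg, seeds=[7, 8])
        zero = table[table.sigma == 0.0].sort_values("replicate")
        assert list(zero["final_alive"]) == base_finals
        assert len(table) == 1 * 2 * 2  # records x sigmas x replicates
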