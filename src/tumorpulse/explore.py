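"""Model-exploration workflow over pulsed-TNF treatment schedules.

The search point is the 3-vector (pulse period, pulse duration, TNF
concentration) inside a box (default: 5-800 min, 5-200 min, 0.001-1 ng/L).
Three strategies are provided:

* :func:`sweep` — a predetermined set of candidates, uniform random or grid;
* :func:`ga_optimize` — a generational genetic algorithm (tournament
  selection, blend crossover, per-gene Gaussian mutation, elitism);
* :func:`cmaes_optimize` — Covariance Matrix Adaptation Evolution Strategy
  with rank-one and rank-mu covariance updates and cumulative step-size
  control, run in box-normalised coordinates with a quadratic boundary
  penalty; the final sampling distribution (mean, C, sigma) is reported.

Fitness is the replicate-averaged final alive cell count (minimised).  The
same replicate seeds are used for every candidate (common random numbers), so
repeated evaluation of a point returns the same value and runs are
reproducible serially or in parallel.  Post-hoc analyses: summary statistics
and Spearman correlations of the effective set, ranking by total supplied
TNF, and the robustness of top treatments under receptor-parameter
heterogeneity.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulation import SimulationConfig, is_effective, score_treatment
from .treatment import SEARCH_BOX, PulseSchedule, total_tnf

__all__ = [
    "SearchSpace",
    "ExplorationRecord",
    "sweep",
    "ga_minimize",
    "ga_optimize",
    "cmaes_minimize",
    "cmaes_optimize",
    "characterize_effective",
    "rank_by_total_tnf",
    "select_top_treatments",
    "robustness_analysis",
    "records_dataframe",
]

PARAM_NAMES = ("period", "duration", "concentration")


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds for (period, duration, concentration)."""

    bounds: tuple = SEARCH_BOX

    def __post_init__(self):
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each axis needs lower < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def schedule(self, x) -> PulseSchedule:
        period, duration, conc = (float(v) for v in x)
        duration = min(duration, period)  # keep duration <= period
        return PulseSchedule(period, duration, conc)


@dataclass
class ExplorationRecord:
    """One evaluated treatment."""

    schedule: PulseSchedule
    finals: list
    fitness: float
    effective: bool
    total_tnf: float
    algorithm: str
    iteration: int
    seed: int


def records_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "period": r.schedule.period, "duration": r.schedule.duration,
        "concentration": r.schedule.concentration, "fitness": r.fitness,
        "effective": r.effective, "total_tnf": r.total_tnf,
        "algorithm": r.algorithm, "iteration": r.iteration, "seed": r.seed,
        **{f"final_{i}": f for i, f in enumerate(r.finals)},
    } for r in records])


def _replicate_seeds(seed: int, n_rep: int) -> list[int]:
    """Common random numbers: the same replicate seeds for every candidate."""
    rng = np.random.Generator(np.random.Philox(key=[int(seed), 0x5EED5]))
    return [int(s) for s in rng.integers(0, 2**31 - 1, n_rep)]


def _make_evaluator(config: SimulationConfig, space: SearchSpace, seed: int,
                    initial: int, algorithm: str):
    rep_seeds = _replicate_seeds(seed, len(config.seeds))

    def evaluate(x, iteration) -> ExplorationRecord:
        sched = space.schedule(space.clip(np.asarray(x, dtype=float)))
        fitness, finals = score_treatment(config, sched, rep_seeds)
        return ExplorationRecord(
            schedule=sched, finals=finals, fitness=fitness,
            effective=is_effective(finals, initial),
            total_tnf=total_tnf(sched, config.horizon),
            algorithm=algorithm, iteration=iteration, seed=seed)

    return evaluate


def _initial_count(config: SimulationConfig) -> int:
    from .population import initialize_disc, initialize_spheroid

    if config.geometry == "disc":
        return len(initialize_disc(config.radius,
                                   config.population.spacing_2d,
                                   config.population.cell_volume))
    return len(initialize_spheroid(config.radius,
                                   config.population.spacing_3d,
                                   config.population.cell_volume))


# ---------------------------------------------------------------------------
# sweep search
# ---------------------------------------------------------------------------

def sample_candidates(space: SearchSpace, n: int, sampler: str,
                      seed: int) -> np.ndarray:
    """n candidate points: 'uniform' per axis, or a near-cubic 'grid'."""
    if n < 0:
        raise ValueError("n must be non-negative")
    lo, hi = space.lower, space.upper
    if sampler == "uniform":
        rng = np.random.Generator(np.random.Philox(key=[int(seed), 0xCAFE]))
        return lo + rng.random((n, 3)) * (hi - lo)
    if sampler == "grid":
        k = max(1, int(np.ceil(n ** (1 / 3))))
        axes = [np.linspace(lo[i], hi[i], k) for i in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        return pts[:n]
    raise ValueError(f"unknown sampler '{sampler}'")


def _eval_point(args) -> ExplorationRecord:
    """Top-level candidate evaluation (picklable for process pools)."""
    config, space, seed, initial, algorithm, x, iteration, rep_seeds = args
    sched = space.schedule(space.clip(np.asarray(x, dtype=float)))
    fitness, finals = score_treatment(config, sched, rep_seeds)
    return ExplorationRecord(
        schedule=sched, finals=finals, fitness=fitness,
        effective=is_effective(finals, initial),
        total_tnf=total_tnf(sched, config.horizon),
        algorithm=algorithm, iteration=iteration, seed=seed)


def sweep(space: SearchSpace, n: int, sampler: str,
          config: SimulationConfig, seed: int,
          workers: int = 1) -> list[ExplorationRecord]:
    """Evaluate n sampled schedules; identical result serially or parallel."""
    pts = sample_candidates(space, n, sampler, seed)
    initial = _initial_count(config)
    rep_seeds = _replicate_seeds(seed, len(config.seeds))
    jobs = [(config, space, seed, initial, "sweep", x, i, rep_seeds)
            for i, x in enumerate(pts)]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as ex:
            return list(ex.map(_eval_point, jobs))
    return [_eval_point(j) for j in jobs]


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAParams:
    pop_size: int = 24
    generations: int = 50
    tournament_k: int = 3
    blend_alpha: float = 0.5
    crossover_prob: float = 0.9
    mutation_sigma_frac: float = 0.1   # fraction of each axis range
    mutation_prob: float = 0.3
    elites: int = 1


def ga_minimize(bounds, fn, params: GAParams, seed: int):
    """Generational real-coded GA minimising fn over a box.

    Returns (best_x, best_f, history) where history rows are
    (generation, best_f, mean_f) and best_f is non-increasing (elitism).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    ndim = len(lo)
    if params.pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    rng = np.random.Generator(np.random.Philox(key=[int(seed), 0x6A6A]))
    pop = lo + rng.random((params.pop_size, ndim)) * (hi - lo)
    fit = np.array([fn(x) for x in pop])
    history = []
    sigma = params.mutation_sigma_frac * (hi - lo)
    for gen in range(params.generations):
        order = np.argsort(fit)
        elites = pop[order[:params.elites]].copy()
        elite_fit = fit[order[:params.elites]].copy()
        children = []
        while len(children) < params.pop_size - params.elites:
            # tournament selection of two parents
            pick = [order[np.min(rng.integers(0, params.pop_size,
                                              params.tournament_k))]
                    for _ in range(2)]
            p1, p2 = pop[pick[0]].copy(), pop[pick[1]].copy()
            if rng.random() < params.crossover_prob:
                # blend (BLX-alpha) crossover
                d = np.abs(p1 - p2)
                lo_c = np.minimum(p1, p2) - params.blend_alpha * d
                hi_c = np.maximum(p1, p2) + params.blend_alpha * d
                child = lo_c + rng.random(ndim) * (hi_c - lo_c)
            else:
                child = p1
            mut = rng.random(ndim) < params.mutation_prob
            child[mut] += rng.normal(0.0, sigma[mut])
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elites, np.array(children)])
        fit = np.concatenate([elite_fit,
                              [fn(x) for x in pop[params.elites:]]])
        history.append((gen, float(fit.min()), float(fit.mean())))
    best = int(np.argmin(fit))
    return pop[best], float(fit[best]), history


def ga_optimize(space: SearchSpace, config: SimulationConfig,
                params: GAParams, seed: int):
    """GA over treatment schedules; returns (records, best_record)."""
    initial = _initial_count(config)
    evaluate = _make_evaluator(config, space, seed, initial, "ga")
    records: list[ExplorationRecord] = []
    cache: dict[tuple, float] = {}

    def fn(x):
        key = tuple(np.round(x, 12))
        if key not in cache:
            rec = evaluate(x, len(records) // params.pop_size)
            records.append(rec)
            cache[key] = rec.fitness
        return cache[key]

    best_x, best_f, history = ga_minimize(space.bounds, fn, params, seed)
    best = min(records, key=lambda r: r.fitness)
    return records, best, history


# ---------------------------------------------------------------------------
# CMA-ES
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CMAParams:
    lam: int = 12                 # population size (lambda)
    iterations: int = 60
    sigma0: float = 0.3           # initial step size, normalised coordinates
    mean0: np.ndarray | None = None  # normalised; default box centre
    ftol: float | None = None     # optional early stop on best fitness


@dataclass
class CMAResult:
    best_x: np.ndarray
    best_f: float
    mean: np.ndarray              # final distribution mean (original coords)
    cov: np.ndarray               # final covariance (normalised coords)
    sigma: float
    evaluations: int
    history: list                 # (iteration, best_f, sigma)
    restarts: int


def cmaes_minimize(bounds, fn, params: CMAParams, seed: int) -> CMAResult:
    """Standard (mu/mu_w, lambda)-CMA-ES with step-size and covariance paths.

    Variables are optimised in [0, 1]^n normalised coordinates; candidates
    outside the box are repaired by clipping and charged a quadratic penalty.
    A degenerate covariance triggers a restart with inflated sigma.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    n = len(lo)
    lam = params.lam
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w ** 2)
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chin = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    rng = np.random.Generator(np.random.Philox(key=[int(seed), 0xC3A]))

    def denorm(z):
        return lo + z * (hi - lo)

    def penalised(z):
        zr = np.clip(z, 0.0, 1.0)
        return fn(denorm(zr)) + 1e6 * float(np.sum((z - zr) ** 2))

    m = (np.full(n, 0.5) if params.mean0 is None
         else np.asarray(params.mean0, dtype=float))
    sigma = params.sigma0
    C = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)
    best_f = np.inf
    best_x = denorm(m)
    evals = 0
    restarts = 0
    history = []
    eigeneval = 0
    B, D = np.eye(n), np.ones(n)

    for it in range(params.iterations):
        if evals - eigeneval > lam / ((c1 + cmu) * n * 10):
            eigeneval = evals
            C = (C + C.T) / 2
            d2, B = np.linalg.eigh(C)
            if (not np.all(np.isfinite(d2))) or d2.min() <= 0 \
                    or d2.max() / max(d2.min(), 1e-300) > 1e14:
                restarts += 1
                C = np.eye(n)
                B, D = np.eye(n), np.ones(n)
                pc[:] = 0.0
                ps[:] = 0.0
                sigma = max(sigma, params.sigma0) * 2.0
            else:
                D = np.sqrt(d2)
        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T
        xs = m + sigma * y
        fs = np.array([penalised(x) for x in xs])
        evals += lam
        order = np.argsort(fs)
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = denorm(np.clip(xs[order[0]], 0.0, 1.0))
        yw = w @ y[order[:mu]]
        m = m + sigma * yw
        # cumulative paths
        invsqrtC_yw = B @ ((B.T @ yw) / D)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * invsqrtC_yw
        hsig = (np.linalg.norm(ps)
                / np.sqrt(1 - (1 - cs) ** (2 * (it + 1))) / chin
                < 1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * yw
        artmp = y[order[:mu]]
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
             + cmu * (artmp.T * w) @ artmp)
        sigma = sigma * np.exp((cs / damps)
                               * (np.linalg.norm(ps) / chin - 1))
        history.append((it, best_f, float(sigma)))
        if params.ftol is not None and best_f <= params.ftol:
            break

    return CMAResult(best_x=best_x, best_f=best_f,
                     mean=denorm(np.clip(m, 0.0, 1.0)), cov=C,
                     sigma=float(sigma), evaluations=evals,
                     history=history, restarts=restarts)


def cmaes_optimize(space: SearchSpace, config: SimulationConfig,
                   params: CMAParams, seed: int):
    """CMA-ES over treatment schedules; returns (records, best, result)."""
    initial = _initial_count(config)
    evaluate = _make_evaluator(config, space, seed, initial, "cmaes")
    records: list[ExplorationRecord] = []
    cache: dict[tuple, float] = {}

    def fn(x):
        key = tuple(np.round(x, 12))
        if key not in cache:
            rec = evaluate(x, len(records))
            records.append(rec)
            cache[key] = rec.fitness
        return cache[key]

    result = cmaes_minimize(space.bounds, fn, params, seed)
    best = min(records, key=lambda r: r.fitness)
    return records, best, result


# ---------------------------------------------------------------------------
# effective-set characterization and robustness
# ---------------------------------------------------------------------------

def characterize_effective(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary statistics and Spearman correlations of effective treatments.

    Returns (stats, correlations): per-parameter mean/sd/min/median/max over
    the effective records, and pairwise Spearman rho with p-values.  An empty
    effective set returns empty frames with a warning.
    """
    import warnings

    from scipy import stats as sps

    df = records_dataframe(records)
    eff = df[df["effective"]] if len(df) else df
    if eff.empty:
        warnings.warn("no effective treatments to characterize",
                      stacklevel=2)
        return pd.DataFrame(), pd.DataFrame()
    rows = [{"parameter": p, "mean": eff[p].mean(), "std": eff[p].std(),
             "min": eff[p].min(), "median": eff[p].median(),
             "max": eff[p].max()} for p in PARAM_NAMES]
    stats = pd.DataFrame(rows).set_index("parameter")
    corr_rows = []
    for i, a in enumerate(PARAM_NAMES):
        for b in PARAM_NAMES[i + 1:]:
            if len(eff) > 1 and eff[a].nunique() > 1 and eff[b].nunique() > 1:
                rho, p = sps.spearmanr(eff[a], eff[b])
            else:
                rho, p = np.nan, np.nan
            corr_rows.append({"param_a": a, "param_b": b, "spearman_rho": rho,
                              "p_value": p})
    return stats, pd.DataFrame(corr_rows)


def rank_by_total_tnf(records, horizon: float | None = None):
    """Effective records sorted by ascending total supplied TNF (ties by
    fitness); non-effective records are excluded."""
    eff = [r for r in records if r.effective]
    if horizon is not None:
        eff = [replace(r, total_tnf=total_tnf(r.schedule, horizon))
               for r in eff]
    return sorted(eff, key=lambda r: (r.total_tnf, r.fitness))


def select_top_treatments(records, k: int = 30,
                          require_eradication: bool = True):
    """Top-k effective treatments for the robustness protocol.

    By default only schedules with zero final tumor cells in every replicate
    qualify; if none eradicates fully, the effective set is used instead.
    Ordered by fitness, ties by total supplied TNF.
    """
    pool = [r for r in records if r.effective]
    if require_eradication:
        zero = [r for r in pool if all(f == 0 for f in r.finals)]
        pool = zero or pool
    return sorted(pool, key=lambda r: (r.fitness, r.total_tnf))[:k]


def robustness_analysis(top_records, sigmas, config: SimulationConfig,
                        seeds=None) -> pd.DataFrame:
    """Re-score treatments under increasing receptor-parameter heterogeneity.

    Returns a long table (treatment x sigma x replicate) of final alive
    counts and % of the initial population.  With sigma=0 and the same seeds
    the baseline finals are reproduced exactly (determinism).
    """
    seeds = list(config.seeds if seeds is None else seeds)
    initial = _initial_count(config)
    rows = []
    for rec_i, rec in enumerate(top_records):
        for sigma in sigmas:
            cfg = replace(config,
                          variability=replace(config.variability,
                                              sigma=float(sigma)))
            _, finals = score_treatment(cfg, rec.schedule, seeds)
            for rep, (s, f) in enumerate(zip(seeds, finals)):
                rows.append({
                    "treatment": rec_i,
                    "period": rec.schedule.period,
                    "duration": rec.schedule.duration,
                    "concentration": rec.schedule.concentration,
                    "sigma": float(sigma), "replicate": rep, "seed": s,
                    "final_alive": f,
                    "pct_alive": 100.0 * f / initial,
                })
    return pd.DataFrame(rows)
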