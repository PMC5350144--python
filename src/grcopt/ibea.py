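"""Indicator-Based Evolutionary Algorithm over maximum-conductance vectors.

The optimization unknowns are the G_i-max densities (plus, optionally,
the calcium-pool decay rate), treated as the genes of a chromosome.  Each
individual is scored by simulating the model at the template stimulus
amplitudes (10, 16, 22 pA), extracting the discharge features, and
z-scoring them against the template; IBEA then ranks individuals by the
pairwise additive-epsilon indicator

    I_eps(a, b) = max_i (a_i - b_i)

(the smallest translation making ``a`` weakly dominate ``b``) through the
exponential fitness

    F(x) = sum_{y != x} -exp(-I(y, x) / (c * kappa)),   c = max |I|.

Selection removes the worst individual and updates the remaining fitness
values until the population size is restored (environmental selection);
mating uses binary tournaments; variation applies per-gene swap
recombination and bounded polynomial mutation.  Optimization runs in
cycles: after each cycle of generations the search range is re-seeded
from the best individuals and the next cycle starts, the final population
being the last generation of the last cycle.  There is no elitism
criterion beyond environmental selection itself.

All randomness flows from one seeded generator; runs are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import simulate_batch
from .features import (FeatureTemplate, MISSING_PENALTY, detect_spikes,
                       extract_features, objective_scores)
from .morphology import CellModel, ParameterRange
from .protocols import OPT_STEP_AMPLITUDES_PA, step_protocol

__all__ = ["OptimizationConfig", "Population", "CycleResult",
           "epsilon_indicator", "ibea_fitness", "environmental_selection",
           "binary_tournament", "vary", "run_optimization", "filter_valid",
           "make_feature_evaluator"]


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass
class OptimizationConfig:
    """IBEA run parameters.

    Defaults follow the granule cell study design: population 150 (mono)
    or 200 (multi), 50 generations per cycle, 10 cycles, individual
    mutation probability 0.5, recombination probability 0.5, per-gene
    swap probability 0.25.  ``kappa`` is the indicator scaling of the
    exponential fitness; ``top_fraction`` and ``range_expand`` control
    the between-cycle range reset.
    """

    population_size: int = 150
    generations: int = 50
    cycles: int = 10
    mutation_prob: float = 0.5
    recombination_prob: float = 0.5
    swap_prob: float = 0.25
    kappa: float = 0.05
    eta_mutation: float = 20.0
    seed: int = 0
    stimuli_pA: tuple[float, ...] = OPT_STEP_AMPLITUDES_PA
    trace_ms: float = 2000.0
    pre_ms: float = 100.0
    dt_ms: float = 0.025
    settle_ms: float = 500.0
    top_fraction: float = 0.1
    range_expand: float = 0.1

    def __post_init__(self):
        for p in (self.mutation_prob, self.recombination_prob,
                  self.swap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size % 2:
            raise ValueError("population size must be even "
                             "(pairwise variation)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class Population:
    """A generation: gene matrix with scores."""

    genes: np.ndarray                     # [N, G]
    objectives: np.ndarray                # [N, D]
    fitness: np.ndarray | None = None     # [N]
    spike_counts: np.ndarray | None = None  # [N, n_stimuli]

    @property
    def size(self) -> int:
        return self.genes.shape[0]

    def objective_sum(self) -> np.ndarray:
        return self.objectives.sum(axis=1)


@dataclass
class CycleResult:
    """Per-generation statistics of one optimization cycle."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_objective_sum: list[float] = field(default_factory=list)
    evaluations: int = 0
    ranges: list[tuple[float, float]] = field(default_factory=list)


# --------------------------------------------------------------------------
# IBEA core
# --------------------------------------------------------------------------

def epsilon_indicator(a: np.ndarray, b: np.ndarray) -> float:
    """Additive epsilon indicator for minimization objectives."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal length")
    return float(np.max(a - b))


def _indicator_matrix(objs: np.ndarray) -> tuple[np.ndarray, float]:
    """Pairwise eps matrix on objectives normalized to [0, 1] per
    dimension; returns (I, c) with I[y, x] = eps(y, x), c = max |I|."""
    lo = objs.min(axis=0)
    span = objs.max(axis=0) - lo
    span[span == 0] = 1.0
    z = (objs - lo) / span
    ind = (z[:, None, :] - z[None, :, :]).max(axis=2)  # I[y, x]
    c = float(np.abs(ind).max())
    return ind, c


def ibea_fitness(objectives: np.ndarray, kappa: float = 0.05) -> np.ndarray:
    """Exponential indicator fitness; higher is better.

    A population of one scores 0 (empty sum).  If all indicator values
    are zero (all-identical objectives) the fitness is uniform.
    """
    objs = np.asarray(objectives, dtype=float)
    n = objs.shape[0]
    if n <= 1:
        return np.zeros(n)
    ind, c = _indicator_matrix(objs)
    if c == 0.0:
        return np.zeros(n)
    e = np.exp(-ind / (c * kappa))
    np.fill_diagonal(e, 0.0)
    return -e.sum(axis=0)


def environmental_selection(pop: Population, target: int,
                            kappa: float = 0.05) -> Population:
    """Iteratively drop the worst-fitness individual (standard IBEA loop)
    until ``target`` remain, updating fitness after each removal.

    Deterministic: ties are broken by the lowest population index.
    """
    n = pop.size
    if n < target:
        raise ValueError("population smaller than target size")
    objs = pop.objectives
    ind, c = _indicator_matrix(objs)
    if c == 0.0:
        keep = np.arange(target)  # documented tie-break: first-k retained
        return Population(pop.genes[keep].copy(), objs[keep].copy(),
                          np.zeros(target),
                          None if pop.spike_counts is None
                          else pop.spike_counts[keep].copy())
    e = np.exp(-ind / (c * kappa))
    np.fill_diagonal(e, 0.0)
    fit = -e.sum(axis=0)
    alive = np.ones(n, dtype=bool)
    for _ in range(n - target):
        idx_alive = np.flatnonzero(alive)
        worst = idx_alive[np.argmin(fit[idx_alive])]
        alive[worst] = False
        fit += e[worst, :]  # remove y's contribution to everyone
    keep = np.flatnonzero(alive)
    out_fit = ibea_fitness(objs[keep], kappa)
    return Population(pop.genes[keep].copy(), objs[keep].copy(), out_fit,
                      None if pop.spike_counts is None
                      else pop.spike_counts[keep].copy())


def binary_tournament(fitness: np.ndarray, n_picks: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Indices selected by binary tournament with replacement; ties go to
    the lower index."""
    a = rng.integers(0, len(fitness), size=n_picks)
    b = rng.integers(0, len(fitness), size=n_picks)
    take_a = (fitness[a] > fitness[b]) | \
             ((fitness[a] == fitness[b]) & (a <= b))
    return np.where(take_a, a, b)


def mutate_gene(value: float, lo: float, hi: float,
                rng: np.random.Generator, eta: float = 20.0) -> float:
    """Bounded polynomial mutation of one gene; zero-width range is a
    no-op."""
    if hi <= lo:
        return value
    u = rng.random()
    span = hi - lo
    if u < 0.5:
        delta = (2 * u) ** (1 / (eta + 1)) - 1
    else:
        delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
    return float(np.clip(value + delta * span, lo, hi))


def vary(parents: np.ndarray, ranges: list[ParameterRange],
         cfg: OptimizationConfig, rng: np.random.Generator) -> np.ndarray:
    """Produce offspring from a parent matrix (pairs in order).

    With probability ``recombination_prob`` a parent pair exchanges each
    gene with probability ``swap_prob``; each child then undergoes
    mutation with probability ``mutation_prob``, perturbing every gene by
    a bounded polynomial step with per-gene probability
    ``mutation_prob``.  Offspring are clipped to the current ranges.
    """
    off = np.array(parents, dtype=float, copy=True)
    n, g = off.shape
    lo = np.array([r.lo for r in ranges])
    hi = np.array([r.hi for r in ranges])
    for i in range(0, n - 1, 2):
        if rng.random() < cfg.recombination_prob:
            swap = rng.random(g) < cfg.swap_prob
            tmp = off[i, swap].copy()
            off[i, swap] = off[i + 1, swap]
            off[i + 1, swap] = tmp
    for i in range(n):
        if rng.random() < cfg.mutation_prob:
            for j in range(g):
                if rng.random() < cfg.mutation_prob:
                    off[i, j] = mutate_gene(off[i, j], lo[j], hi[j], rng,
                                            cfg.eta_mutation)
    return np.clip(off, lo, hi)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def make_feature_evaluator(model: CellModel, template: FeatureTemplate,
                           cfg: OptimizationConfig):
    """Build the simulation-based evaluator.

    Returns ``evaluate(gmat) -> (objectives [N, D], spike_counts [N, S])``.
    The whole population runs as one lock-step batch per call, sweeping
    individuals x stimulus amplitudes; simulation failures (non-finite
    traces) yield penalty objectives for the affected individual only.
    """
    stimuli = tuple(sorted(cfg.stimuli_pA))
    proto = step_protocol(1.0, duration_ms=cfg.trace_ms, pre_ms=cfg.pre_ms,
                          post_ms=0.0)
    window = (cfg.pre_ms, cfg.pre_ms + cfg.trace_ms)

    def evaluate(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gmat = np.asarray(gmat, dtype=float)
        n = gmat.shape[0]
        s = len(stimuli)
        big_g = np.repeat(gmat, s, axis=0)
        scale = np.tile(np.array(stimuli), n)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, vmat = simulate_batch(model, big_g, proto, dt=cfg.dt_ms,
                                     settle_ms=cfg.settle_ms,
                                     stim_scale=scale)
        objs = np.empty((n, 0))
        rows = []
        counts = np.zeros((n, s), dtype=int)
        for i in range(n):
            fsets = {}
            for k, stim in enumerate(stimuli):
                v = vmat[i * s + k]
                if not np.all(np.isfinite(v)):
                    fsets[stim] = None
                    continue
                sp = detect_spikes((t, v))
                counts[i, k] = sp.n
                fsets[stim] = extract_features((t, v), sp, window,
                                               stimulus_pA=stim)
            rows.append(objective_scores(fsets, template))
        return np.vstack(rows), counts

    return evaluate


def filter_valid(pop: Population,
                 min_spikes: int = 1) -> tuple[Population, float]:
    """Keep individuals that spiked at every test amplitude.

    Returns the valid subset and the valid fraction.  Models that stay
    silent at any of the three currents are not granule cells and are
    discarded regardless of fitness rank.
    """
    if pop.spike_counts is None:
        raise ValueError("population has no spike counts; evaluate first")
    ok = (pop.spike_counts >= min_spikes).all(axis=1)
    frac = float(ok.mean()) if pop.size else 0.0
    sub = Population(pop.genes[ok].copy(), pop.objectives[ok].copy(),
                     None if pop.fitness is None else pop.fitness[ok].copy(),
                     pop.spike_counts[ok].copy())
    return sub, frac


# --------------------------------------------------------------------------
# the full run
# --------------------------------------------------------------------------

def _reset_ranges(pop: Population, current: list[ParameterRange],
                  initial: list[ParameterRange],
                  cfg: OptimizationConfig) -> list[ParameterRange]:
    """Between-cycle range reset: envelope of the top-fraction individuals
    (by fitness), expanded by ``range_expand`` of its width, clipped to
    the initial +/-50% envelope."""
    k = max(2, int(np.ceil(cfg.top_fraction * pop.size)))
    order = np.argsort(-pop.fitness, kind="stable")[:k]
    top = pop.genes[order]
    out = []
    for j, (r0, _) in enumerate(zip(initial, current)):
        lo = float(top[:, j].min())
        hi = float(top[:, j].max())
        pad = cfg.range_expand * max(hi - lo, 1e-12)
        lo, hi = lo - pad, hi + pad
        lo = max(lo, r0.lo)
        hi = min(hi, r0.hi)
        if hi - lo < 1e-9 * (r0.hi - r0.lo):
            mid = 0.5 * (lo + hi)
            half = 0.5e-9 * (r0.hi - r0.lo) + 1e-12
            lo, hi = mid - half, mid + half
        out.append(ParameterRange(r0.name, r0.compartment, lo, hi))
    return out


def run_optimization(model: CellModel | None, template: FeatureTemplate | None,
                     cfg: OptimizationConfig, evaluator=None,
                     ranges: list[ParameterRange] | None = None,
                     progress=None) -> tuple[list[CycleResult], Population]:
    """Run ``cfg.cycles`` cycles of ``cfg.generations`` IBEA generations.

    ``evaluator`` (gmat -> (objectives, spike_counts or None)) defaults
    to the simulation-based feature evaluator; tests substitute analytic
    toys.  Returns per-cycle statistics and the final population (last
    generation of the last cycle), with fitness and spike counts.
    Simulation failures never abort the run: they score the penalty.
    """
    if evaluator is None:
        if model is None or template is None:
            raise ValueError("need a model and template (or an evaluator)")
        evaluator = make_feature_evaluator(model, template, cfg)
    if ranges is None:
        if model is None:
            raise ValueError("need a model (or explicit ranges)")
        ranges = model.parameter_ranges()
    initial = list(ranges)
    current = list(ranges)
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

    def evaluate_cached(gmat):
        gmat = np.asarray(gmat, dtype=float)
        need = [i for i in range(gmat.shape[0])
                if gmat[i].tobytes() not in cache]
        n_new = len(need)
        if need:
            objs, counts = evaluator(gmat[need])
            counts = (np.zeros((n_new, 1), dtype=int)
                      if counts is None else counts)
            for k, i in enumerate(need):
                cache[gmat[i].tobytes()] = (objs[k], counts[k])
        pairs = [cache[gmat[i].tobytes()] for i in range(gmat.shape[0])]
        return (np.array([p[0] for p in pairs]),
                np.array([p[1] for p in pairs]), n_new)

    results: list[CycleResult] = []
    pop: Population | None = None
    npop = cfg.population_size
    for cycle in range(cfg.cycles):
        lo = np.array([r.lo for r in current])
        hi = np.array([r.hi for r in current])
        genes = lo + (hi - lo) * rng.random((npop, len(current)))
        objs, counts, n_ev = evaluate_cached(genes)
        pop = Population(genes, objs, ibea_fitness(objs, cfg.kappa), counts)
        res = CycleResult(ranges=[(r.lo, r.hi) for r in current])
        res.evaluations += n_ev
        for gen in range(cfg.generations):
            parents = pop.genes[binary_tournament(pop.fitness, npop, rng)]
            off = vary(parents, current, cfg, rng)
            oobjs, ocounts, n_ev = evaluate_cached(off)
            res.evaluations += n_ev
            merged = Population(
                np.vstack([pop.genes, off]),
                np.vstack([pop.objectives, oobjs]),
                None,
                np.vstack([pop.spike_counts, ocounts]))
            pop = environmental_selection(merged, npop, cfg.kappa)
            res.best_fitness.append(float(pop.fitness.max()))
            res.mean_fitness.append(float(pop.fitness.mean()))
            res.best_objective_sum.append(float(pop.objective_sum().min()))
            if progress is not None:
                progress(cycle, gen, res)
        results.append(res)
        if cycle < cfg.cycles - 1:
            current = _reset_ranges(pop, current, initial, cfg)
    return results, pop
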