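"""Offline rate-distortion optimization of the quantization table (GA + PSO).

A quantization table is an individual of 64 chromosomes (one step per
spectrum position), constrained to powers of two in {1, ..., 128}.  The
fitness to *minimise* is the Lagrangian rate-distortion objective

    J(Q) = MSE(Q) + lambda * BR(Q)

with MSE the spatial-domain reconstruction error over a training corpus
of blocks and BR the entropy-coded bits per pixel of the quantized
levels.  Each generation applies, in order: mutation, selection,
crossover, selection (the classic GA loop), then a PSO acceleration step
that pulls every individual toward the generation best b and the global
best g:

    d_{i+1} = w d_i + k (b - v_i) + k (g - v_i),   v_{i+1} = v_i + d_{i+1}

after which chromosomes snap back to the nearest allowed step value.
Elitism re-injects the best individual seen so far, so the best-so-far
fitness trace is monotone non-increasing.  Velocities follow surviving
individuals through selection and reset to zero for crossover offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .entropy import ScanOrder, default_scan_order, payload_bit_length
from .errors import ConfigurationError, InputShapeError
from .quantize import QTable, dequantize, quantize
from .transform import dct3d_fast_batch, idct3d_fast_batch

__all__ = [
    "ALLOWED_STEPS",
    "Individual",
    "RdConfig",
    "SearchState",
    "RdEvaluator",
    "rd_objective",
    "ga_generation",
    "pso_accelerate",
    "optimize_qtable",
]

#: chromosome alphabet: power-of-two quantization steps
ALLOWED_STEPS = np.array([1, 2, 4, 8, 16, 32, 64, 128], dtype=np.int64)


@dataclass
class Individual:
    """64 step chromosomes plus the cached rate-distortion fitness."""

    chromosomes: np.ndarray
    fitness: float = np.inf

    def copy(self) -> "Individual":
        return Individual(self.chromosomes.copy(), self.fitness)

    def qtable(self) -> QTable:
        return QTable(self.chromosomes.reshape(4, 4, 4))


@dataclass(frozen=True)
class RdConfig:
    """Search hyper-parameters; rates in [0, 1], sizes positive."""

    lam: float = 20.0           # Lagrange multiplier on bits/pixel
    max_generations: int = 500
    population_size: int = 32
    mutation_rate: float = 0.05
    crossover_rate: float = 0.8
    tournament_size: int = 3
    w: float = 0.7              # PSO inertia
    k: float = 0.5              # PSO attraction gain
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ConfigurationError("population must contain at least 2 individuals")
        if self.max_generations < 1 or self.tournament_size < 1:
            raise ConfigurationError("sizes must be positive")


@dataclass
class SearchState:
    population: list
    velocities: np.ndarray      # (population, 64) real
    best_of_generation: Individual
    best_overall: Individual
    generation: int = 0


class RdEvaluator:
    """Caches the training spectra and reference pixels for fast fitness calls."""

    def __init__(
        self,
        blocks: np.ndarray,
        lam: float,
        order: ScanOrder | None = None,
    ) -> None:
        blocks = np.asarray(blocks, dtype=np.float64)
        if blocks.ndim != 4 or blocks.shape[1:] != (4, 4, 4) or not blocks.shape[0]:
            raise InputShapeError(
                f"training corpus must be non-empty (n, 4, 4, 4), got {blocks.shape}"
            )
        self.reference = blocks
        self.spectra = dct3d_fast_batch(blocks)
        self.lam = lam
        self.order = order or default_scan_order()
        self.n_pixels = 64 * blocks.shape[0]

    def objective(self, q: QTable) -> float:
        levels = quantize(self.spectra, q)
        recon = idct3d_fast_batch(dequantize(levels, q))
        mse = float(np.mean((recon - self.reference) ** 2))
        bpp = payload_bit_length(levels, self.order) / self.n_pixels
        return mse + self.lam * bpp

    def __call__(self, chromosomes: np.ndarray) -> float:
        return self.objective(QTable(chromosomes.reshape(4, 4, 4)))


def rd_objective(
    q: QTable,
    spectra: np.ndarray,
    lam: float,
    order: ScanOrder | None = None,
) -> float:
    """MSE + lambda * bits-per-pixel for one table over a spectrum corpus."""
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.ndim != 4 or spectra.shape[1:] != (4, 4, 4) or not spectra.shape[0]:
        raise InputShapeError(f"expected non-empty (n, 4, 4, 4), got {spectra.shape}")
    order = order or default_scan_order()
    levels = quantize(spectra, q)
    recon = idct3d_fast_batch(dequantize(levels, q))
    reference = idct3d_fast_batch(spectra)
    mse = float(np.mean((recon - reference) ** 2))
    bpp = payload_bit_length(levels, order) / (64 * spectra.shape[0])
    return mse + lam * bpp


def _snap_to_allowed(values: np.ndarray) -> np.ndarray:
    """Round each entry to the nearest allowed step value."""
    idx = np.abs(values[..., None] - ALLOWED_STEPS[None, :]).argmin(axis=-1)
    return ALLOWED_STEPS[idx]


def _tournament(pop, rng: np.random.Generator, size: int) -> int:
    contenders = rng.integers(0, len(pop), size=size)
    return int(min(contenders, key=lambda i: pop[i].fitness))


def _update_bests(state: SearchState) -> None:
    gen_best = min(state.population, key=lambda ind: ind.fitness)
    state.best_of_generation = gen_best.copy()
    if gen_best.fitness < state.best_overall.fitness:
        state.best_overall = gen_best.copy()


def init_state(evaluator, cfg: RdConfig, rng: np.random.Generator) -> SearchState:
    pop = []
    for _ in range(cfg.population_size):
        chrom = rng.choice(ALLOWED_STEPS, size=64)
        pop.append(Individual(chrom, evaluator(chrom)))
    vel = np.zeros((cfg.population_size, 64))
    state = SearchState(pop, vel, pop[0].copy(), pop[0].copy())
    _update_bests(state)
    return state


def ga_generation(
    state: SearchState,
    cfg: RdConfig,
    rng: np.random.Generator,
    evaluator=None,
) -> SearchState:
    """One GA sweep: mutation, selection, crossover, selection (+ elitism)."""
    if len(state.population) < 2:
        raise ConfigurationError("population must contain at least 2 individuals")
    if evaluator is None:
        raise ConfigurationError("ga_generation requires a fitness evaluator")
    pop = [ind.copy() for ind in state.population]
    vel = state.velocities.copy()

    # mutation: resample chromosomes from the allowed step set
    for ind in pop:
        mask = rng.random(64) < cfg.mutation_rate
        if mask.any():
            ind.chromosomes[mask] = rng.choice(ALLOWED_STEPS, size=int(mask.sum()))
            ind.fitness = evaluator(ind.chromosomes)

    # selection
    keep = [_tournament(pop, rng, cfg.tournament_size) for _ in pop]
    pop = [pop[i].copy() for i in keep]
    vel = vel[keep]

    # crossover: single-point exchange between consecutive pairs
    for a in range(0, len(pop) - 1, 2):
        if rng.random() < cfg.crossover_rate:
            point = int(rng.integers(1, 64))
            ca, cb = pop[a].chromosomes, pop[a + 1].chromosomes
            ca[point:], cb[point:] = cb[point:].copy(), ca[point:].copy()
            pop[a].fitness = evaluator(ca)
            pop[a + 1].fitness = evaluator(cb)
            vel[a] = 0.0
            vel[a + 1] = 0.0

    # selection again
    keep = [_tournament(pop, rng, cfg.tournament_size) for _ in pop]
    pop = [pop[i].copy() for i in keep]
    vel = vel[keep]

    # elitism: the best individual ever seen always survives
    if state.best_overall.fitness < min(ind.fitness for ind in pop):
        worst = int(max(range(len(pop)), key=lambda i: pop[i].fitness))
        pop[worst] = state.best_overall.copy()
        vel[worst] = 0.0

    new_state = SearchState(
        pop, vel, state.best_of_generation, state.best_overall, state.generation + 1
    )
    _update_bests(new_state)
    return new_state


def pso_accelerate(
    state: SearchState,
    cfg: RdConfig,
    evaluator=None,
) -> SearchState:
    """PSO velocity update toward the generation best and global best."""
    if state.best_of_generation is None or state.best_overall is None:
        raise ConfigurationError("PSO requires generation and overall bests")
    if evaluator is None:
        raise ConfigurationError("pso_accelerate requires a fitness evaluator")
    b = state.best_of_generation.chromosomes.astype(np.float64)
    g = state.best_overall.chromosomes.astype(np.float64)
    pop = [ind.copy() for ind in state.population]
    vel = state.velocities.copy()
    for i, ind in enumerate(pop):
        v = ind.chromosomes.astype(np.float64)
        d = cfg.w * vel[i] + cfg.k * (b - v) + cfg.k * (g - v)
        moved = _snap_to_allowed(v + d)
        vel[i] = d
        if not np.array_equal(moved, ind.chromosomes):
            ind.chromosomes = moved
            ind.fitness = evaluator(moved)

    # elitism across the PSO move as well
    if state.best_overall.fitness < min(ind.fitness for ind in pop):
        worst = int(max(range(len(pop)), key=lambda i: pop[i].fitness))
        pop[worst] = state.best_overall.copy()
        vel[worst] = 0.0

    new_state = SearchState(
        pop, vel, state.best_of_generation, state.best_overall, state.generation
    )
    _update_bests(new_state)
    return new_state


def optimize_qtable(
    training: np.ndarray,
    cfg: RdConfig | None = None,
    order: ScanOrder | None = None,
) -> tuple:
    """Run the full hybrid search over a corpus of spatial 4x4x4 blocks.

    Returns ``(QTable, trace)`` where ``trace[i]`` is the best-so-far
    objective after generation ``i`` (monotone non-increasing).
    """
    cfg = cfg or RdConfig()
    evaluator = RdEvaluator(training, cfg.lam, order)
    rng = np.random.default_rng(cfg.seed)
    state = init_state(evaluator, cfg, rng)
    trace = []
    for _ in range(cfg.max_generations):
        state = ga_generation(state, cfg, rng, evaluator)
        state = pso_accelerate(state, cfg, evaluator)
        trace.append(state.best_overall.fitness)
    return state.best_overall.qtable(), np.array(trace)
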