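"""Evolutionary loop: conjugation, fitness-weighted division, uniform culling.

Every iteration each cell takes exactly one action: a mature cell
(``G >= M``) self-conjugates with probability ``S`` (its heritable ``X``
and ``E`` mutate, ``N`` is recomputed from ``E``, its age counters reset);
otherwise, if old enough (``A >= I``), it divides with probability equal
to its fitness, adding an identical daughter to the pool; otherwise it
just ages.  After all cells are processed, ``pop_size`` survivors are
drawn uniformly at random, independent of fitness.  Daughters produced in
an iteration join the pool but are not themselves processed until the
next iteration.

The population is stored as parallel numpy arrays and the whole iteration
is vectorized; the module also exposes the equivalent per-cell operations
(:func:`mutate_clamped`, :func:`attempt_conjugation`,
:func:`attempt_division`) on :class:`~amitosim.model.CellState`, which
define the reference semantics the array path implements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    MAX_ELIMINATION,
    AssortmentModel,
    CellState,
    SimParams,
    chromosome_number_from_elimination,
    fitness_components_arrays,
    total_fitness,
)

__all__ = [
    "Population",
    "PopulationSummary",
    "ExtinctionError",
    "initialize_population",
    "mutate_clamped",
    "attempt_conjugation",
    "attempt_division",
    "cull",
    "run_simulation",
    "summaries_to_frame",
]


class ExtinctionError(RuntimeError):
    """Raised when the population dies out before the run completes."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"population extinct at iteration {iteration}")


@dataclass
class Population:
    """Struct-of-arrays population state.

    All arrays share one length (the current cell count).  ``X``, ``E``
    and ``N`` are heritable genome properties; ``G`` and ``A`` are age
    counters.
    """

    X: np.ndarray
    E: np.ndarray
    N: np.ndarray
    G: np.ndarray
    A: np.ndarray
    iteration: int = 0

    def __len__(self) -> int:
        return len(self.X)

    def cells(self) -> list[CellState]:
        """Materialize the population as a list of CellState (small pops only)."""
        return [
            CellState(X=float(x), E=float(e), N=float(n), G=int(g), A=int(a))
            for x, e, n, g, a in zip(self.X, self.E, self.N, self.G, self.A)
        ]


@dataclass(frozen=True)
class PopulationSummary:
    """Per-iteration population summary (means, medians, spreads, fitness)."""

    iteration: int
    mean_X: float
    median_X: float
    std_X: float
    mean_E: float
    median_E: float
    std_E: float
    mean_N: float
    median_N: float
    std_N: float
    mean_Fdna: float
    mean_Fimb: float
    mean_F: float
    frac_mature: float


def initialize_population(params: SimParams) -> Population:
    """Founding population: pop_size identical cells with X = X0, E = 0,
    N = N0, G = A = 0 (each has fitness 1)."""
    n = params.pop_size
    return Population(
        X=np.full(n, float(params.X0)),
        E=np.zeros(n),
        N=np.full(n, float(params.N0)),
        G=np.zeros(n, dtype=np.int64),
        A=np.zeros(n, dtype=np.int64),
    )


def mutate_clamped(value: float, sd: float, lo: float, hi: float, rng: np.random.Generator) -> float:
    """Normal mutation centred on the parent value, clamped to [lo, hi].

    A draw outside the bounds is reassigned to the violated bound, not
    resampled; sd = 0 returns the value unchanged.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if lo > hi:
        raise ValueError("need lo <= hi")
    draw = value if sd == 0 else rng.normal(value, sd)
    return min(max(draw, lo), hi)


def attempt_conjugation(
    cell: CellState, params: SimParams, rng: np.random.Generator
) -> tuple[bool, CellState]:
    """Self-conjugation attempt: mature cells (G >= M) conjugate with
    probability S, mutating X and E, recomputing N and resetting G = A = 0.

    Returns (conjugated, cell); the cell is returned unchanged when the
    attempt fails.  No partner is involved and nothing is exchanged.
    """
    if cell.G < params.M or rng.random() >= params.S:
        return False, cell
    X = mutate_clamped(cell.X, params.Sd_copy, 0.0, np.inf, rng)
    E = mutate_clamped(cell.E, params.Sd_elim, 0.0, MAX_ELIMINATION, rng)
    return True, CellState(X=X, E=E, N=chromosome_number_from_elimination(E, params.N0), G=0, A=0)


def attempt_division(
    cell: CellState, params: SimParams, rng: np.random.Generator
) -> tuple[CellState | None, CellState]:
    """Asexual division attempt for a cell that did not conjugate this
    iteration.

    With probability ``total_fitness(cell)``, a cell of age A >= I divides:
    both it and the identical daughter get G+1, A+1.  Otherwise only the
    iteration age advances.  Returns (daughter or None, updated cell).
    """
    if cell.A >= params.I and rng.random() < total_fitness(cell, params):
        parent = CellState(X=cell.X, E=cell.E, N=cell.N, G=cell.G + 1, A=cell.A + 1)
        daughter = CellState(X=cell.X, E=cell.E, N=cell.N, G=parent.G, A=parent.A)
        return daughter, parent
    return None, CellState(X=cell.X, E=cell.E, N=cell.N, G=cell.G, A=cell.A + 1)


def cull(population: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """Uniformly sample pop_size survivors, independent of fitness.

    Pools at or below pop_size survive intact; an empty pool signals
    extinction.
    """
    n = len(population)
    if n == 0:
        raise ExtinctionError(population.iteration)
    if n <= params.pop_size:
        return population
    keep = rng.choice(n, size=params.pop_size, replace=False)
    return Population(
        X=population.X[keep],
        E=population.E[keep],
        N=population.N[keep],
        G=population.G[keep],
        A=population.A[keep],
        iteration=population.iteration,
    )


def _summarize(pop: Population, params: SimParams, assortment: AssortmentModel) -> PopulationSummary:
    f_dna, f_imb = fitness_components_arrays(pop.X, pop.E, pop.N, pop.G, params, assortment)
    return PopulationSummary(
        iteration=pop.iteration,
        mean_X=float(pop.X.mean()),
        median_X=float(np.median(pop.X)),
        std_X=float(pop.X.std()),
        mean_E=float(pop.E.mean()),
        median_E=float(np.median(pop.E)),
        std_E=float(pop.E.std()),
        mean_N=float(pop.N.mean()),
        median_N=float(np.median(pop.N)),
        std_N=float(pop.N.std()),
        mean_Fdna=float(f_dna.mean()),
        mean_Fimb=float(f_imb.mean()),
        mean_F=float((f_dna * f_imb).mean()),
        frac_mature=float((pop.G >= params.M).mean()),
    )


def step(
    pop: Population, params: SimParams, rng: np.random.Generator, assortment: AssortmentModel
) -> Population:
    """Advance the population by one iteration (conjugation, division, culling)."""
    n = len(pop)

    # Conjugation pass: mature cells conjugate with probability S.
    conj = (pop.G >= params.M) & (rng.random(n) < params.S)
    idx = np.flatnonzero(conj)
    if idx.size:
        if params.Sd_copy > 0:
            pop.X[idx] = np.maximum(rng.normal(pop.X[idx], params.Sd_copy), 0.0)
        if params.Sd_elim > 0:
            pop.E[idx] = np.clip(rng.normal(pop.E[idx], params.Sd_elim), 0.0, MAX_ELIMINATION)
        pop.N[idx] = chromosome_number_from_elimination(pop.E[idx], params.N0)
        pop.G[idx] = 0
        pop.A[idx] = 0

    # Division pass over non-conjugators of sufficient age.
    eligible = ~conj & (pop.A >= params.I)
    f_dna, f_imb = fitness_components_arrays(pop.X, pop.E, pop.N, pop.G, params, assortment)
    divide = eligible & (rng.random(n) < f_dna * f_imb)

    # Non-conjugators age by one; dividers additionally advance a generation
    # and contribute an identical daughter to the pool.
    pop.A[~conj] += 1
    pop.G[divide] += 1
    d = np.flatnonzero(divide)

    pool = Population(
        X=np.concatenate([pop.X, pop.X[d]]),
        E=np.concatenate([pop.E, pop.E[d]]),
        N=np.concatenate([pop.N, pop.N[d]]),
        G=np.concatenate([pop.G, pop.G[d]]),
        A=np.concatenate([pop.A, pop.A[d]]),
        iteration=pop.iteration,
    )
    survivors = cull(pool, params, rng)
    survivors.iteration = pop.iteration + 1
    return survivors


def run_simulation(
    params: SimParams,
    record_every: int = 100,
    rng: np.random.Generator | None = None,
) -> list[PopulationSummary]:
    """Run the full evolutionary simulation and return recorded summaries.

    Records a :class:`PopulationSummary` for the founding state and then
    every ``record_every`` iterations plus the final iteration.  Fully
    deterministic given (params, seed).
    """
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    rng = rng or np.random.default_rng(params.seed)
    assortment = AssortmentModel()
    pop = initialize_population(params)
    out = [_summarize(pop, params, assortment)]
    for it in range(1, params.n_iter + 1):
        pop = step(pop, params, rng, assortment)
        if it % record_every == 0 or it == params.n_iter:
            out.append(_summarize(pop, params, assortment))
    return out


def summaries_to_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    """Stack recorded summaries into a tidy DataFrame (one row per record)."""
    return pd.DataFrame([s.__dict__ for s in summaries])
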