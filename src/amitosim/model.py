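"""Core fitness and genome-structure equations of the macronuclear evolution model.

The model tracks, for each ciliate cell, a handful of heritable and
age-related quantities: the per-type chromosome copy number ``X``, the
fraction of micronuclear DNA eliminated when the macronucleus (MAC) is
rebuilt ``E``, the number of distinct chromosome types ``N`` (a
deterministic function of ``E``), the vegetative generation number ``G``
(amitotic divisions since the last conjugation) and the iteration age
``A``.  Fitness is the product of two penalties:

* a DNA-content cost ``F_DNA = min(1, (X0 / (X (1-E)))**K)`` — cells whose
  total retained MAC DNA exceeds the founding content divide more slowly;
* an imbalance cost ``F_imb = (1 - q_G**X)**(N*P)`` — a Kimura-style
  probability that no chromosome type has been completely lost after ``G``
  rounds of amitosis, used as a proxy for the fitness cost of copy-number
  imbalances.

``q_G`` is the extinction probability after ``G`` generations of the
critical Galton–Watson branching process with offspring law
Binomial(2, 1/2): under amitosis every chromosome copy is duplicated and
each of the two resulting copies independently follows one daughter with
probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimParams",
    "CellState",
    "AssortmentModel",
    "PARAM_RANGES",
    "MAX_ELIMINATION",
    "MAX_CHROMOSOMES",
    "chromosome_number_from_elimination",
    "extinction_probability",
    "dna_fitness",
    "imbalance_fitness",
    "total_fitness",
]

#: Upper bound on the elimination coefficient; more elimination is lethal.
MAX_ELIMINATION = 0.98

#: Chromosome number reached at maximal elimination — approximately the
#: number of genes in spirotrich macronuclei (one gene per chromosome).
MAX_CHROMOSOMES = 20_000.0

#: Documented sweep ranges for each population-level parameter.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "X0": (10, 50),
    "N0": (35, 75),
    "Sd_copy": (5, 50),
    "Sd_elim": (0.01, 0.05),
    "I": (0, 4),
    "M": (5, 20),
    "K": (0.1, 1.0),
    "P": (0.5, 2.0),
    "S": (0.01, 0.1),
}


@dataclass(frozen=True)
class SimParams:
    """Population-level simulation parameters.

    Parameters
    ----------
    X0 : float
        Initial copy number (copies per chromosome type).
    N0 : float
        Initial chromosome number (distinct types in the founding MAC).
    Sd_copy : float
        Standard deviation of the copy-number mutation applied at
        conjugation (copies).
    Sd_elim : float
        Standard deviation of the elimination-coefficient mutation
        (fraction).
    I : int
        Minimum iteration age required before a cell may divide.
    M : int
        Minimum generation number required before a cell may conjugate.
    K : float
        Exponent weighting the DNA-content fitness cost.
    P : float
        Weight of the imbalance fitness cost (exponent multiplier on the
        chromosome number).
    S : float
        Per-iteration conjugation probability for mature cells.
    pop_size : int
        Number of cells kept after culling each iteration.
    n_iter : int
        Number of iterations to simulate.
    seed : int
        RNG seed; a run is fully reproducible from (params, seed).
    """

    X0: float = 10.0
    N0: float = 50.0
    Sd_copy: float = 5.0
    Sd_elim: float = 0.01
    I: int = 2
    M: int = 15
    K: float = 0.2
    P: float = 1.0
    S: float = 0.02
    pop_size: int = 1000
    n_iter: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("X0", "N0", "K", "P"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        # zero sds / zero S are degenerate but valid: mutation or conjugation disabled
        for name in ("Sd_copy", "Sd_elim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.S <= 1:
            raise ValueError(f"S must be in [0, 1], got {self.S}")
        if self.I < 0:
            raise ValueError(f"I must be >= 0, got {self.I}")
        if self.M < 0:
            raise ValueError(f"M must be >= 0, got {self.M}")
        if self.pop_size < 1:
            raise ValueError(f"pop_size must be >= 1, got {self.pop_size}")
        if self.n_iter < 0:
            raise ValueError(f"n_iter must be >= 0, got {self.n_iter}")

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class CellState:
    """State of a single ciliate cell.

    ``X``, ``E`` and ``N`` are fixed between conjugations; ``G`` counts
    asexual divisions since the last conjugation and ``A`` counts
    iterations since the last conjugation (so ``A >= G`` always).
    """

    X: float
    E: float
    N: float
    G: int = 0
    A: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.E <= MAX_ELIMINATION:
            raise ValueError(f"E must lie in [0, {MAX_ELIMINATION}], got {self.E}")
        if self.X < 0:
            raise ValueError(f"X must be >= 0, got {self.X}")
        if self.G < 0 or self.A < self.G:
            raise ValueError(f"need 0 <= G <= A, got G={self.G}, A={self.A}")


class AssortmentModel:
    """Memoized extinction probabilities of a single chromosome-copy lineage.

    Under amitosis a copy is duplicated and each duplicate independently
    follows the tracked daughter with probability 1/2, i.e. the lineage is
    a critical Galton–Watson process with offspring law Binomial(2, 1/2).
    Its extinction probability after ``g`` divisions obeys

        q_0 = 0,   q_{g+1} = ((1 + q_g) / 2) ** 2,

    the iterate of the offspring generating function f(s) = ((1+s)/2)**2.
    The sequence increases strictly to 1 with the critical-process
    asymptotics g * (1 - q_g) -> 4.
    """

    def __init__(self) -> None:
        self._q = np.zeros(1)

    def _extend(self, g_max: int) -> None:
        if g_max < len(self._q):
            return
        q = np.empty(g_max + 1)
        q[: len(self._q)] = self._q
        for g in range(len(self._q), g_max + 1):
            q[g] = ((1.0 + q[g - 1]) / 2.0) ** 2
        self._q = q

    def q(self, G: int) -> float:
        """Extinction probability q_G of one copy's lineage after G divisions."""
        if G < 0 or G != int(G):
            raise ValueError(f"G must be a non-negative integer, got {G}")
        G = int(G)
        self._extend(G)
        return float(self._q[G])

    def q_array(self, G: np.ndarray) -> np.ndarray:
        """Vectorized lookup of q_G for an integer array of generation counts."""
        G = np.asarray(G)
        if G.size and G.min() < 0:
            raise ValueError("G must be non-negative")
        if G.size:
            self._extend(int(G.max()))
        return self._q[G]


_ASSORTMENT = AssortmentModel()


def extinction_probability(G: int) -> float:
    """Probability that a single chromosome copy's lineage has died out
    after ``G`` amitotic divisions (see :class:`AssortmentModel`)."""
    return _ASSORTMENT.q(G)


def chromosome_number_from_elimination(E, N0):
    """Map the elimination coefficient to the macronuclear chromosome number.

    Chromosome number grows exponentially with the fraction of DNA
    eliminated, pinned by two fixed points: no elimination leaves the
    micronuclear chromosome number ``N0``, and maximal elimination
    (E = 0.98, the spirotrich extreme) fragments the genome into one
    chromosome per gene, ~20,000:

        N(E) = N0 * (20000 / N0) ** (E / 0.98)

    Accepts scalars or arrays.
    """
    E = np.asarray(E, dtype=float)
    N0 = np.asarray(N0, dtype=float)
    if np.any(E < 0) or np.any(E > MAX_ELIMINATION):
        raise ValueError(f"E must lie in [0, {MAX_ELIMINATION}]")
    if np.any(N0 <= 0):
        raise ValueError("N0 must be strictly positive")
    out = N0 * (MAX_CHROMOSOMES / N0) ** (E / MAX_ELIMINATION)
    return float(out) if out.ndim == 0 else out


def dna_fitness(X: float, E: float, X0: float, K: float) -> float:
    """DNA-content fitness penalty, min(1, (X0 / (X (1-E)))**K).

    ``X * (1 - E)`` is the cell's total MAC DNA relative to one genome
    equivalent; the founding population (X = X0, E = 0) has content X0 and
    fitness 1.  Cells holding more DNA than the founders divide more
    slowly; holding less cannot raise fitness above 1.  A cell with no MAC
    DNA (X = 0) is inviable and gets fitness 0.
    """
    if E < 0 or E >= 1:
        raise ValueError(f"E must lie in [0, 1), got {E}")
    if X0 <= 0 or K <= 0:
        raise ValueError("X0 and K must be strictly positive")
    if X < 0:
        raise ValueError(f"X must be >= 0, got {X}")
    if X == 0:
        return 0.0
    return min(1.0, (X0 / (X * (1.0 - E))) ** K)


def imbalance_fitness(X: float, N: float, G: int, P: float) -> float:
    """Chromosome-imbalance fitness penalty, (1 - q_G**X)**(N*P).

    This is the probability that none of ``N`` independent chromosome
    types, each starting with ``X`` copies, has been completely lost after
    ``G`` amitotic divisions (each copy's lineage dying out independently
    with probability ``q_G``), raised to the weight ``P``.  At P = 1 it is
    exactly the Kimura retention probability.  A freshly conjugated cell
    (G = 0) has a balanced MAC and fitness 1.
    """
    if X < 0 or N <= 0 or P <= 0:
        raise ValueError("need X >= 0, N > 0, P > 0")
    if G < 0 or G != int(G):
        raise ValueError(f"G must be a non-negative integer, got {G}")
    if G == 0:
        return 1.0
    q = extinction_probability(int(G))
    return (1.0 - q**X) ** (N * P)


def total_fitness(cell: CellState, params: SimParams) -> float:
    """Division probability of a cell: F = F_DNA * F_imb, in [0, 1]."""
    return dna_fitness(cell.X, cell.E, params.X0, params.K) * imbalance_fitness(
        cell.X, cell.N, cell.G, params.P
    )


def fitness_components_arrays(
    X: np.ndarray,
    E: np.ndarray,
    N: np.ndarray,
    G: np.ndarray,
    params: SimParams,
    assortment: AssortmentModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (F_DNA, F_imb) for parallel arrays of cell state.

    Identical semantics to :func:`dna_fitness` / :func:`imbalance_fitness`
    applied element-wise; used by the population engine.
    """
    assortment = assortment or _ASSORTMENT
    retained = X * (1.0 - E)
    with np.errstate(divide="ignore"):
        f_dna = np.where(
            retained > 0, np.minimum(1.0, (params.X0 / np.maximum(retained, 1e-300)) ** params.K), 0.0
        )
    q = assortment.q_array(G)
    # q_0 = 0 and X may be 0; 0**0 is ambiguous, so pin G == 0 to fitness 1.
    with np.errstate(invalid="ignore"):
        f_imb = np.where(G == 0, 1.0, (1.0 - q**X) ** (N * params.P))
    return f_dna, f_imb
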