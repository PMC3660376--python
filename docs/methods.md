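# Methods

## Model

Each cell carries five state variables: copy number `X` (copies per
chromosome type, real-valued), elimination coefficient `E ∈ [0, 0.98]`
(fraction of micronuclear DNA removed when the macronucleus is rebuilt),
chromosome number `N` (a deterministic function of `E`), generation number
`G` (amitotic divisions since the last conjugation) and iteration age `A`
(iterations since the last conjugation, so `A ≥ G`). `X` and `E` are
heritable and change only at conjugation; `N` is recomputed from `E` at
the same moment.

**Chromosome-number map.** `N(E) = N0 · (20000/N0)^(E/0.98)`, exponential
in `E` and pinned by two anchors: no elimination keeps the micronuclear
chromosome count `N0`, and maximal elimination (98%, the spirotrich
extreme) fragments the genome into one chromosome per gene (~20,000).
Small eliminations therefore fragment little, large ones
disproportionately much. `N` is kept real-valued; nothing downstream
needs an integer count.

**Imbalance penalty.** Under amitosis each chromosome copy is duplicated
and each duplicate independently follows a given daughter with probability
½, so a single copy's lineage is a critical Galton–Watson process with
offspring law Binomial(2, ½). Its extinction probability after `g`
divisions satisfies `q_0 = 0`, `q_{g+1} = ((1+q_g)/2)²` (the iterate of
the offspring generating function). The probability that none of `N`
independent types, each seeded with `X` copies, has been completely lost
after `G` divisions is `(1 − q_G^X)^N`; the fitness term raises it to the
weight `P`:

    F_imb = (1 − q_G^X)^(N·P)

We compute `q_G` by the exact recursion (memoized up to the largest `G`
seen, O(G_max) once per run) rather than an asymptotic closed form, so the
term is exact at small `G` where most divisions happen. The recursion
satisfies the critical-branching law `G·(1 − q_G) → 4`, which the tests
check at `G = 10⁴`. `F_imb` is pinned to 1 at `G = 0` (a freshly rebuilt
MAC is balanced by construction; this also resolves the `0⁰` ambiguity at
`X = 0`), and a cell with `X = 0` and `G ≥ 1` has `F_imb = 0`.

Where `P` enters was an open design choice (only "a weight" is
biologically specified); we place it as an exponent multiplier on `N`, so
`P = 1` recovers the unmodified retention probability and `P` scales the
per-type log-penalty.

**DNA-content penalty.** `F_DNA = min(1, (X0/(X·(1−E)))^K)`. `X·(1−E)` is
the cell's total MAC DNA in units where the founding content is `X0`;
holding more DNA than the founders slows division, holding less cannot
raise fitness above 1 (the cap). On the surface `X·(1−E) = X0` the penalty
is exactly 1; with `E` pinned at 0.98 and `X0 = 10` that surface is
`X = 500`, the cost-free ploidy ceiling the simulations approach.
`X = 0` is representable (mutation clamps at zero) and treated as
inviable (`F_DNA = 0`) rather than an error, so such cells persist until
culled.

**Total fitness** `F = F_DNA · F_imb` is the per-iteration division
probability.

## Population loop

Each iteration every cell takes one action:

1. *Conjugation*: if `G ≥ M`, with probability `S` the cell self-conjugates
   — `X ← clamp(Normal(X, Sd_copy), 0, ∞)`,
   `E ← clamp(Normal(E, Sd_elim), 0, 0.98)` (out-of-range draws are
   reassigned to the violated bound, not resampled), `N ← N(E)`,
   `G ← 0`, `A ← 0`. No partner and no exchange: pairing rules would add
   parameters the data cannot pin down.
2. *Division*: otherwise, if `A ≥ I`, with probability `F` the cell
   divides — `G` and `A` increase by one and an identical copy joins the
   pool. Reaching age `I` suffices (`A ≥ I`).
3. *Aging*: otherwise only `A` increases.
4. *Culling*: after all cells are processed, `pop_size` survivors are
   drawn uniformly without replacement, independent of fitness. Daughters
   join the pool but are not processed until the next iteration.

Founding cells start at `X = X0, E = 0, N = N0, G = A = 0` (fitness 1,
mimicking a near-diploid, karyorelict-like non-dividing MAC) and must wait
`I` iterations before their first division, consistent with the
post-conjugation recovery rule.

The whole iteration is vectorized over numpy arrays (struct-of-arrays
population); the per-cell operations exposed in the API define the
reference semantics and are tested against the array path's invariants.
Since cells do not interact within an iteration except through the uniform
cull, processing order is immaterial. A run uses a single `default_rng`
stream seeded from `SimParams.seed` and is bit-reproducible; replicates
and sweep settings derive non-colliding seeds via `SeedSequence` keys
`(base_seed, setting_index, replicate)`.

Because parents always survive to the cull, literal extinction (an empty
pool) cannot occur; the observable failure mode of unfit populations is
fitness collapse, which sweep outputs flag when the final-window mean
fitness drops below 0.01.

## Parameters

| name | meaning | unit | default | sweep range |
|---|---|---|---|---|
| `X0` | founding copy number | copies/type | 10 | 10–50 |
| `N0` | founding chromosome number | types | 50 | 35–75 |
| `Sd_copy` | copy-number mutation sd | copies | 5 | 5–50 |
| `Sd_elim` | elimination mutation sd | fraction | 0.01 | 0.01–0.05 |
| `I` | minimum age to divide | iterations | 2 | 0–4 |
| `M` | maturity to conjugate | generations | 15 | 5–20 |
| `K` | DNA-cost exponent | — | 0.2 | 0.1–1.0 |
| `P` | imbalance weight | — | 1 | 0.5–2 |
| `S` | conjugation probability | /iteration | 0.02 | 0.01–0.1 |

Population size 1,000 and budget 100,000 iterations are the study
conditions; `Sd_copy = Sd_elim = 0` and `S = 0` are admitted as degenerate
mutation-off / conjugation-off configurations used by invariance tests.

## Assortment oracle

The evolutionary engine never tracks per-chromosome counts. The oracle
does: per replicate it initializes `N` counts at `X` and per division
replaces each count `c` by a `Binomial(2c, ½)` draw, following one
daughter lineage (symmetry makes that sufficient for retention
probabilities, at cost linear in `G`). Splitting is independent per type —
no constraint that a daughter receives exactly half the total DNA. The
fraction of replicates retaining all types estimates the retention
probability; agreement with `(1 − q_G^X)^N` is scored as a z-discrepancy
in units of the binomial standard error under the closed-form value
(using the null value keeps the test defined when zero successes are
expected), flagged beyond 3 SE. The tests run the full grid
`(X, N, G) ∈ {1,2,5,10}×{1,5,50}×{1,2,5,10}` at 10⁵ replicates.

## Convergence detection

"Reaching a stable distribution" is operationalized as windowed-mean
stability: a recorded series has converged at the first iteration after
which its rolling mean (window 2,000 iterations by default, converted to
recorded rows) stays within a relative tolerance (default 5%) of its final
value, requiring at least one full window of stability after that point
(otherwise a still-rising ramp would "converge" at its last sample).
End-state summaries average the final 1,000 iterations.

## Problem sizes and what the tests show

Unit and property tests use small populations (50–300 cells, a few
hundred iterations). The end-to-end tests run the study conditions:
default-parameter runs use 3 seeds × 40,000 iterations (the trajectory
stabilizes at roughly 12,000–17,000 iterations for `E` and 30,000–40,000
for `X`, so the final window sits past both), and the one-at-a-time sweep
(endpoints of the `K`, `S`, `N0` ranges, 3 replicates) uses the full
100,000-iteration budget, because stabilization *timing* — unlike the end
state — varies strongly with both seed and parameter setting and shorter
budgets measure timing rather than the end state. `scripts/acceptance.py`
likewise uses 3 × 100,000 iterations.

The simulation is its own synthetic world; no empirical data enters. What
passing tests show is internal: the closed-form imbalance proxy matches
explicit binomial assortment, and the claimed evolutionary outcome
(near-maximal elimination, ~20,000 chromosomes, ~50-fold ploidy increase)
emerges reproducibly from the stated dynamics. They cannot show that real
macronuclear evolution followed these dynamics.

## Limitations

* Conjugation is selfing; real pair formation, partner exchange and
  micronuclear genetics are not modeled.
* Imbalance cost is complete-loss probability only; dose-dependent
  (partial-imbalance) fitness effects are ignored, as is copy-number
  regulation during vegetative growth of the kind described in
  *Paramecium* and *Tetrahymena*.
* All chromosome types share one copy number; the oracle's independent
  binomial splitting is the only assortment mechanism considered
  (a total-DNA-conserving hypergeometric variant is not implemented).
* The exponential `N(E)` map and the functional forms of the two fitness
  penalties are modeling reconstructions pinned by their boundary
  behavior, kept behind single functions so alternates can be swapped.
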