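# amitosim

Agent-based simulation of ciliate macronuclear genome evolution.

Ciliates carry two nuclei: a diploid germline micronucleus (MIC) and a
polyploid somatic macronucleus (MAC) that divides by *amitosis* — a
spindle-free, stochastic partitioning of duplicated chromosomes between
daughter nuclei. In several lineages (spirotrichs most famously) the MAC
is spectacularly reorganized: ~98% of the micronuclear DNA is eliminated,
the genome is fragmented into ~20,000 single-gene "nanochromosomes", and
each is amplified to high copy number. `amitosim` simulates a population
model in which this architecture emerges from the competition between just
two costs:

* **chromosome imbalance** — after `G` amitotic divisions, a cell with `N`
  chromosome types of copy number `X` retains all types with probability
  `(1 − q_G^X)^N` (Kimura's retention probability), where `q_G` is the
  extinction probability of a single copy's lineage under the critical
  branching process with offspring law Binomial(2, ½):
  `q_0 = 0`, `q_{g+1} = ((1 + q_g)/2)²`. Few copies and many chromosome
  types make loss (and imbalance generally) more likely;
* **DNA content** — replicating a MAC holding more DNA than the founding
  content slows division: `F_DNA = min(1, (X0 / (X·(1−E)))^K)`, where `E`
  is the fraction of MIC DNA eliminated when the MAC is rebuilt.

A cell's fitness — its per-iteration division probability — is the product
`F = F_DNA · F_imb` with `F_imb = (1 − q_G^X)^(N·P)`. Chromosome number is
slaved to elimination through the exponential map
`N(E) = N0 · (20000/N0)^(E/0.98)`, pinned at `N(0) = N0` (no elimination,
micronuclear chromosome count) and `N(0.98) = 20000` (one chromosome per
gene). Each iteration, mature cells (`G ≥ M`) self-conjugate with
probability `S` — mutating the heritable `X` and `E` by clamped normal
draws, rebuilding a balanced MAC and resetting their age counters — other
cells of sufficient age divide with probability `F`, and the population is
culled uniformly back to 1,000 cells, independent of fitness.

Starting from a near-diploid, karyorelict-like founding state
(`X = 10, N = 50, E = 0`), evolving populations repeatedly discover the
spirotrich solution: `E` pinned near its 0.98 ceiling, ~20,000 chromosomes,
and copy number amplified ~50-fold toward the DNA-cost-free ceiling
`X = X0/(1−E) = 500`.

The package also contains the brute-force counterpart the closed form
replaces: a per-chromosome binomial-assortment Monte-Carlo simulator, used
as an independent oracle to validate the imbalance formula.

## Worked example

```python
from amitosim import SimParams, run_simulation, summaries_to_frame

params = SimParams(n_iter=100_000, seed=1)   # defaults: X0=10, N0=50, ...
traj = summaries_to_frame(run_simulation(params, record_every=100))
tail = traj.tail(10)
print(f"mean E = {tail.mean_E.mean():.4f}")
print(f"mean N = {tail.mean_N.mean():.0f}")
print(f"mean X = {tail.mean_X.mean():.0f}")
```

prints

```
mean E = 0.9792
mean N = 19903
mean X = 489
```

i.e. the population ends with ~98% of micronuclear DNA eliminated, a MAC
fragmented into ~19,900 chromosome types, and copy number amplified from
10 to ~490 — a ~49-fold ploidy increase, just under the 500-copy ceiling
at which total DNA content matches the founding state.

The same run is available from the shell, along with a parameter sweep and
the assortment oracle:

```bash
amitosim run --iterations 100000 --seed 1 --out runs/
amitosim oracle --types 5 --copies 2 --generations 3 --reps 100000
amitosim sweep --spec sweep.yaml --out sweep_out/
amitosim report runs/run_seed1.manifest.json
```

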