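# grnmod

Simulation and analysis pipeline for studying how **structural modularity
evolves in gene regulatory networks as a byproduct of specialization in
gene activity**, and how modularity in turn facilitates **co-option** of
evolved modules — for computational and systems biologists working on the
evolution of developmental gene networks.

## The model in brief

A genotype is a signed interaction matrix `w` over `N = 10` genes
(`w[i,j] ∈ {−1, 0, +1}`, the effect of gene `j` on gene `i`).  Binary gene
activities `s ∈ {−1, +1}^N` develop synchronously:

```
s_i(t+1) = +1  if  Σ_j w[i,j] s_j(t) > 0,   −1 otherwise
```

Phenotypes are fixed-point attractors.  Fitness rewards robust attainment
of reference activity patterns: initial states are perturbations of a
target `s*` (per-gene flip probability 0.15), each trajectory contributes
`γ = (1 − D_H(A, s*)/N)^5` when it settles at fixed point `A` (0 for
cycles), and the per-pattern fitness is the mean over 500 sampled
trajectories; several selected patterns combine additively.  Populations
of 100 networks evolve by fitness-proportional reproduction and a biased
gain/loss mutation operator (per-gene rate 0.05, loss probability
`4r/(4r + N − r)` for a gene with `r` regulators) that holds connectivity
at 2–3 regulators per gene.

Structural modularity of an evolved network is Newman's
`Q = Σ_s [l_s/L − (d_s/2L)²]` maximized over partitions of the undirected
projection of `w`, normalized against 1,000 degree-preserving
randomizations: `Qm = (Q − ⟨Q_rand⟩)/(max Q_rand − ⟨Q_rand⟩)`.

The package's experiments show that selecting a *second* activity pattern
that shares some gene states with the first drives `Qm` up (specialization
→ modularity), that the resulting modules collect genes whose activity
changes concertedly, that a third pattern splits them further, and that a
new pattern recombining evolved module states is acquired far faster than
a random one (modularity → co-option).

## Worked example

```python
import numpy as np
from grnmod import (EvolutionParams, FitnessParams, Phase, SelectionRegime,
                    evolve, normalized_modularity, project_to_graph)
from grnmod.fixtures import fig_pair_patterns

I, II = fig_pair_patterns()          # II shares genes 0-4 with I, differs at 5-9
regime = SelectionRegime([Phase(500, [I]), Phase(3000, [I, II])])
trace = evolve(regime, EvolutionParams(), FitnessParams(n_trajectories=100),
               seed=3)

for gen in (500, 3500):
    net = trace.best_network(gen)
    res = normalized_modularity(project_to_graph(net), n_null=1000,
                                rng=np.random.default_rng(0))
    print(f"gen {gen}: fitness={trace.max_fitness[gen]:.2f} "
          f"Q={res.q:.2f} Qm={res.q_normalized:.2f}")
```

prints:

```
gen 500: fitness=1.00 Q=0.14 Qm=-0.17
gen 3500: fitness=0.95 Q=0.32 Qm=0.32
```

After the single-pattern phase the best network attains pattern I robustly
(fitness 1.0) but is no more modular than degree-matched random graphs
(`Qm < 0`); after 3,000 further generations selecting both patterns it
attains both (fitness 0.95) and now sits well above its nulls
(`Qm ≈ 0.3`), with the module boundary separating the shared-state genes
from the concertedly switching ones.  Single populations drift — the
modularity of the momentary best network fluctuates — so the claim-level
comparisons run replicate populations and paired signed-rank tests; those
drivers (including the controls and the co-option experiment) live in
`grnmod.experiments` and run in `tests/test_acceptance.py`.

There is also a CLI for the same operations:

```
grnmod fixtures --set pair --out patterns.txt
grnmod evolve --config run.yaml --out results/
grnmod modularity results/best_network.txt --n-null 1000
grnmod stats qm.tsv --before qm_gen500 --after qm_gen3500
```

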