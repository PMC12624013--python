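# pillarsim

Agent-based simulation of bacterial growth and motility in pillar-structured
two-dimensional microhabitats — lattice analogues of the pore networks that
soil aggregates create.

Soil aggregates produce pores spanning micrometres to millimetres, with an
approximately fractal size distribution, and microbial activity concentrates
in and around them.  `pillarsim` models this setting the way microfluidic
"soil-on-a-chip" experiments do: circular pillars (soil particles) stand in a
flat square field, and bacteria grow in the remaining pore space.  The
package generates the pillar arrangements (fractal, uniform array, pillar-free
bulk, and block-like aggregates of *n*×*n* pillars with intra-block gap *d*),
runs a stochastic growth model on them, and computes the statistics used to
compare arrangements: growth curves, pillar-periphery partitions, box-counting
dimension, single-walker motility distributions, and two-strain coexistence
probabilities.

## Model

Each bacterium occupies one pixel of a 256 × 256 field and carries a
duplication energy $E_D \in [0, 1]$.  Per time step, agents are processed in
random order; each agent

1. dies with probability $\delta$ (default 0.01),
2. picks one of its 8 Moore neighbours uniformly and moves there iff the
   pixel is inside the field, not a pillar, and unoccupied,
3. updates its energy, $E_D \leftarrow \mathrm{clip}(E_D + g - c \cdot
   \mathbb{1}[\text{moved}],\, 0,\, 1)$, with growth rate $g = 0.1$ and
   movement cost $c$ (default 0.09; zero when energy consumption is
   disabled),
4. duplicates when $E_D = 1$ and an empty neighbour exists: the daughter
   starts at $E_D = 0$ on a uniform empty neighbour and the parent resets to
   $E_D = 0$.

Because movement drains energy, freely moving bacteria duplicate more slowly
than bacteria whose movement is blocked by pillars: with $c = g - \delta$
free movers sit exactly at replacement while pore-confined cells stay
strongly super-critical, which is what makes densely pillared (fractal,
block-like) arrangements outgrow open fields once consumption is switched
on.

## Worked example

```python
import numpy as np
from pillarsim import ArrangementSpec, SimParams, make_layout
from pillarsim.arrangements import box_counting_dimension
from pillarsim.motility import distribution_mode, motility_ensemble
from pillarsim.simulator import run_replicates

fractal = make_layout(ArrangementSpec("fractal"))
print("pillars:", fractal.pillar_count)
print("box-counting dimension:",
      round(box_counting_dimension(fractal.obstacle_mask).dimension, 3))

ens = run_replicates(fractal, SimParams(t_max=150, seed=11), n_reps=20)
print("median count at t=150:", np.median(ens.counts_at(150)))

walkers = motility_ensemble(fractal, n_runs=1000, horizon=500, seed=2)
print("modal p_outside:", distribution_mode([w.p_outside for w in walkers]))
print("median D_tot:", np.median([w.d_tot for w in walkers]))
```

prints

```
pillars: 144
box-counting dimension: 1.73
median count at t=150: 93.0
modal p_outside: 0.9750000000000001
median D_tot: 484.0
```

The fractal arrangement holds 144 pillars (matching the 12 × 12 uniform
array), and its obstacle mask has a box-counting dimension of 1.73.  With
energy consumption enabled, growth is slow at first — a median of 93 of the
100 initial cells at t = 150 — but that is already more than the array (~74)
or bulk (~47) fields retain under the same energy budget, and the
pore-confined fractal population keeps compounding afterwards (median ≈1700
by t = 400) while the others stay flat or decline.  Of 1000
independent 500-step walkers, the most common fate is roaming the open
corridors (modal fraction of time outside the 3-px pillar periphery 0.975)
while a minority stays trapped inside pillar clusters; walkers successfully
move in 484 of 500 steps at the median.

The same experiments are scriptable from the shell:

```bash
pillarsim generate-arrangement --kind fractal --out runs/fractal
pillarsim simulate --arrangement runs/fractal --energy on --reps 20 --t-max 150 --seed 11 --out runs/growth
pillarsim motility --arrangement runs/fractal --runs 1000 --seed 2 --out runs/motility
pillarsim reproduce-figure fig6A --reps 1000 --seed 2 --out runs/fig6A
```

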