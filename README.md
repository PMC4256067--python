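# devwta

Developmental self-construction and self-calibration of soft
winner-take-all (sWTA) cortical networks, simulated end to end: a single
precursor cell carrying a five-gene regulatory network expands into a mixed
excitatory/inhibitory population, grows axons and dendrites in 3D space,
forms synapses wherever complementary neurites come within 2 µm, and then
tunes its synaptic weights — first by homeostatic synaptic scaling while
growth is still ongoing, then by BCM learning under patterned input — into
a recurrent circuit that amplifies its strongest inputs and suppresses the
rest.

The package is for computational neuroscientists who want to study how
genetically encoded local rules (kinetic gene networks, growth-cone
guidance, proximity synaptogenesis, homeostatic and Hebbian plasticity)
jointly produce functional cortical circuitry, without any global
controller.

## The model in brief

* **Lineage.** Five gene products per cell; Hill-function kinetics
  `psi(c) = (c^n + bK^n)/(c^n + K^n)` combined with soft-logic gates.  The
  intrinsic production rate of the progenitor gene sets the number of
  symmetric divisions `n1 = floor(log2(N))`; a secondary division cycle
  with probability `P2 = (N - 2^n1)/2^n1` makes the expected final count
  exactly `N`.  Fates are excitatory with probability 0.8.
* **Morphogenesis.** Somata uniform in a cube (~61,000/mm³); one axon and
  three dendrites per neuron; growth cones mix 0.75 of their previous
  direction with 0.25 random, taper with every move and branch, and stop at
  a minimal diameter.  Axons chemotax on a screened-Poisson substance field
  secreted by opposite-class somata, retracting below concentration 1e-8
  and regrowing above 0.036.  Synapses form at bouton–spine pairs within
  2 µm (no autapses).
* **Electrophysiology.** Linear-threshold rate units,
  `tau dr/dt = -r + max(0, s + x + W r)`, Euler-integrated, rates clipped
  to [0, 250] Hz.  Connection weights are summed synapse weights, capped at
  `n_syn x 0.1`.
* **Plasticity.** Homeostatic phase: multiplicative synaptic scaling
  `dw = eta (a_goal - abar) w` toward class targets, concurrent with growth.
  Specification phase: BCM with sliding threshold
  `dw = eta r_pre r_post (r_post - theta) w`, `theta = <r^2>/a_goal`, on all
  synapses onto excitatory neurons; scaling continues onto inhibitory ones.
  Weight changes clamp at 3% per step.
* **Function.** Moving-hill (retinal-wave-like) or discrete-bar inputs
  drive learning; the learned network is characterized by its recurrent
  gain, banded weight topology, response decorrelation, orientation
  selectivity index, and the concentration of inhibition (REE = activity ×
  connection weight).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Grow the standard 250-neuron network (200 excitatory + 50 inhibitory in a
160 µm cube) and inspect its connectivity:

```python
import numpy as np
from devwta.morphogenesis import (place_somata, grow_network, form_synapses,
                                  connectivity_stats)

rng = np.random.default_rng(1)
somata = place_somata(200, 50, 160.0, rng)
growth = grow_network(somata, seed=rng)          # ~30 s on one core
synapses = form_synapses(growth)
stats = connectivity_stats(synapses, somata.is_excitatory)
print(f"synapses: {len(synapses)}")
print(f"E->E per excitatory neuron: {stats['mean_counts_per_post']['EE']:.1f}")
print(f"mean % excitatory inputs:   {stats['mean_pct_excitatory_inputs']:.1f}")
```

```
synapses: 45108
E->E per excitatory neuron: 161.2
mean % excitatory inputs:   83.3
```

Each excitatory neuron receives on the order of 150 excitatory synapses
from other excitatory neurons, and across the population about 84% of a
neuron's input synapses are excitatory — the grown network reproduces the
measured excitatory/inhibitory composition of superficial cortex without
any tuning of the connectivity itself.

A full developmental run through both learning phases (reduced scale,
117E/30I) and its functional readout:

```python
from devwta.pipeline import PRESETS, DevelopmentalRun
from devwta.analysis import network_gain

run = DevelopmentalRun(PRESETS["wta_waves"]).run_standard()   # ~3 min
gain = network_gain(run.state, run.somata.is_excitatory)
print(f"recurrent gain of the learned WTA: {gain:.2f}")
```

```
recurrent gain of the learned WTA: 1.74
```

A gain near 1.8 means the winning neuron fires ~80% above its feed-forward
drive: recurrent excitation amplifies the winner while shared inhibition
suppresses the losers below theirs.

The same presets are available from the command line:

```bash
devwta simulate wta_waves --seed 1 --checkpoint ckpt/ --report report.json
devwta analyze ckpt/learned.h5 --outdir analysis/
```

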