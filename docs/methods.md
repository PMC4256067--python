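# Methods

This note describes the models implemented in `devwta`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.  Default problem sizes are the ones used by the
test suite and by `scripts/acceptance.py`.

## Gene regulatory network and lineage

Each cell carries five gene products (G0, G1, G2, GE, GI) whose
concentrations follow production/degradation kinetics integrated with
explicit Euler (dt = cell_cycle_time/1000; the system is non-stiff at the
default rates).  Regulatory interactions act through Hill binding
probabilities

    psi(c) = (c^n + b K^n) / (c^n + K^n)

with affinity K, cooperativity n and basal bias b, combined through the
soft-logic gates AND(p,q) = pq, OR(p,q) = p+q−pq, NOT(p) = 1−p.  The edge
structure is G0→G1, G1→{GE, GI, G2}, G2→{GE, GI}; no cross-repression is
modeled.  G0 is constitutive and equilibrates within a small fraction of the
first cell cycle; G1 accumulates at the intrinsic rate `alpha1`.

Cells divide on a fixed clock.  Immediately after each division a cell
checks G1 against the differentiation threshold 0.99; `calibrate_alpha1`
bisects on the forward-simulated crossing time so that the threshold is
reached during cycle `n1`, replacing manual tuning.  At the decision, a cell
enters one extra division cycle with probability P2 (activating G2),
otherwise differentiates immediately; differentiation activates GE with
probability `ei_ratio` (default 0.8, the cortical ~4:1 ratio), else GI.
With `n1 = floor(log2(n_target))` and `P2 = (n_target − 2^n1)/2^n1` the
expected leaf count is exactly `2^n1 (1 + P2) = n_target`; the realized
count is `2^n1 + Binomial(2^n1, P2)`.  Fate decisions are modeled as single
categorical draws at threshold crossing rather than stochastic chemistry —
a deliberate simplification that preserves the statistics of interest.
Every cell draws from its own RNG stream derived from the master seed, so
lineage topology is reproducible regardless of traversal order.

## Morphogenesis

Somata (8 µm diameter) are placed uniformly in a cube; the default side is
chosen for 61,000 neurons/mm³, inside the observed cortical range
(40,000–86,900).  Each neuron sprouts one axon and three dendrites in
uniform random directions.  Growth cones advance in steps of ν/2 = 3.5 µm
(two steps per 7 µm segment).  The new direction mixes the previous
direction (weight 0.75) with a uniform random unit vector (0.25).  Diameters
shrink by Δd_move per step and Δd_bif per bifurcation (per-class values per
the growth-parameter table); a cone stops below the class minimum d_min.
Per step a cone bifurcates with probability p_b0 + p_bc·C, where C is the
local guidance-substance concentration.

Axons read a substance secreted by somata of the opposite cell class and
retract (5 µm per unit time, versus 100 for growth) when the local
concentration falls below 1e-8, resuming above 0.036.  The substance field
is the analytic steady state of diffusion with first-order degradation
(D = 50, k = 5): each source contributes `Q/(4πDr)·exp(−r√(k/D))`, capped
at the soma radius.  Since somata never move, the field is static; the
growth engine samples it from a trilinearly interpolated lattice (4 µm
spacing, 60 µm margin) for speed, and the exact kernel is available for
point queries and tests.  The secretion rate Q is not an observable of the
original preparation; it is calibrated once so that a single source reaches
the retraction-stop threshold at 20 µm, which makes the tabulated
thresholds operative at inter-soma distances.

Mechanical physics (forces, viscosity, adhesion) is not simulated; the
morphology is kinematic.  Retraction consumes the cone's own unbranched
tail only: segments bearing synapses, branch points, and segments other
cones are rooted on all anchor the arbor (physically, synaptic contacts and
sibling branches hold a neurite in place).  An axon that retracts all the
way to its soma is a degenerate axon and stops.

Initial neurite diameters are **not** tabulated constants; they are the
model's arbor-size calibration.  The defaults (excitatory axon 2.45,
inhibitory axon 1.56, dendrites 2.4 µm) were set so that a standard
200E + 50I growth in a 160 µm cube reproduces the observed connectivity
statistics (mean ≈ 84% excitatory input synapses; ≈ 155 E→E synapses per
excitatory neuron).  Inhibitory axons, with their higher taper and strongly
concentration-dependent branching, form dense local baskets near excitatory
somata; inhibitory arbors are spatially smaller than excitatory ones.

Boutons and spines sit at the midpoints of axonal and dendritic segments.
A synapse forms for every bouton–spine pair within 2 µm that does not
belong to one neuron (no autapses); a spatial index (cKDTree) makes this
O(n log n), and an all-pairs scan serves as the test oracle.  Excitatory
and inhibitory synapses start at weights 0.001 and 0.01.  Synapses are
never rearranged or pruned.

## Rate dynamics

Neurons are linear-threshold units, τ dr/dt = −r + max(0, s + x + Σw·r − T)
with τ = 1, T = 0, integrated by explicit Euler and clipped to [0, 250] Hz.
During learning each presentation is relaxed with dt = 0.1 τ; analyses use
dt = 0.05 τ or smaller with more iterations.  During the specification
phase the relaxation is deliberately long (1000 iterations = 100 τ): a
nearly-critical recurrent mode grows slowly, and only a long relaxation
lets it express itself in the rates so that the sliding BCM threshold can
rein it in.  With short relaxations the learned network can hide
supercritical modes that only explode at analysis time.

Connection weights are the sums of their constituent synapse weights.  Each
connection's magnitude is capped at `n_syn × 0.1` (the maximal weight of a
single synapse).  The input layer is fully connected; input
projections are not grown, so they carry no synapse count — they are
treated as two-synapse connections (cap 0.2), keeping the single
per-synapse maximum of 0.1 as the only weight bound in the model.  This
bound is what puts the learned network in the cap-limited regime where the
winner's rate sits well below the BCM fixed point, correlated weights ride
their caps, and the recurrent gain is set by the cap structure rather than
by a fragile interior equilibrium.  A direct active-set solver for the
piecewise-linear fixed point provides an independent oracle on small
instances.

## Plasticity

**Synaptic scaling** (homeostatic phase, and onto inhibitory neurons
throughout): dw = (dt/τ_scal)(a_goal − ā)·w, applied to all of a neuron's
input weights.  Below target, excitatory and inhibitory drive both grow in
magnitude; above target both shrink.  Because every input weight is
multiplied by a common factor, each neuron's excitation/inhibition ratio is
preserved — the balance laid down by synaptogenesis survives homeostasis.
(The alternative reading, scaling excitation and inhibition in opposite
directions, destroys inhibition whenever the target is approached from
below and cannot produce a balanced network; see the test suite's
convergence tests.)  The average ā is the arithmetic mean over a ring
buffer of the last N steady-state rates, N = one full stimulus period
(2 × number of inputs for waves, 2 × number of patterns for discrete
stimuli; the factor 2 reflects active/non-active alternation).

**BCM** (specification phase, synapses onto excitatory neurons; the
`all-bcm` variant routes every synapse here): dw = (dt/τ_bcm)·r_pre·r_post·
(r_post − θ)·w with sliding threshold θ = ⟨r²⟩/a_goal.  A constant rate is
stationary exactly at r = a_goal.  Linearity in the signed weight means a
correlated inhibitory connection onto an excitatory neuron strengthens
(becomes more negative), which concentrates inhibition onto few dominant
inhibitory afferents.  Both rules are linear in the weight, so evolving the
summed matrix equals evolving individual synapses and summing — verified
to floating tolerance in the tests.

Every learning step is clamped to 3% of the current weight magnitude.  One
learning step follows each full stimulus period, with the Hebbian term
averaged over the period's presentations.  Time constants are expressed as
per-period learning rates (η_scal = 0.5, η_bcm = 0.05); with the 3% clamp
these mostly act as step-direction selectors and the clamp sets the pace,
mirroring the original description of slow (hours-to-days) adaptation
compressed into fewer, clamped steps.  Because learning fires once per
period in both stimulus modes, the wave and pattern scenarios use the same
per-period rates (the 8× time-constant ratio of the original formulation
compensated for its 8× higher learning cadence with discrete patterns).

The inhibitory target is `a_goal_I = 2 × a_goal_E`; only "higher than
excitatory" is empirically constrained, so the factor is a model choice.
Larger factors (e.g. 4×) ask the inhibitory population for rates the grown
excitatory drive cannot sustain, which destabilizes the homeostatic state
and, downstream, the learned topology; 2× keeps both phases in their
stable regimes.

## Developmental sequence

Growth, synapse formation and scaling run concurrently: growth advances in
epochs of 100 steps, new synapses are summed into the weight matrix at
their initial weights, and learning runs a few periods per epoch.  This
concurrency is load-bearing: synapses arriving while rates already hover
near target create the sustained above-target pressure under which scaling
builds inhibition; running homeostasis only after growth leaves the
network unbalanced.  The patterned input attaches after 30% of growth
(config-exposed); before that the network is driven by spontaneous
activity alone (uniform [0, 0.06] Hz per presentation, redrawn each time).
After growth ends the homeostatic phase continues to convergence, then the
specification phase applies the BCM routing.  Neurons that received no
inhibitory synapses are reported and excluded from learned-network
analyses.

## Stimuli

Waves: 20 input populations on a ring; the hill's center fires at 1.4 Hz
and decays with ring distance by the profile [1, 0.5, 0.25, 0.125] (the
0.5 at distance 1 is prescribed; the geometric continuation at distances 2
and 3 is the package's choice, stored as a single profile array);
populations beyond distance 3 fire uniformly in [0, 0.06] Hz.  The center
advances one population per active presentation and wraps.  Ring position
doubles as orientation angle in [0°, 180°).  Discrete stimuli: 8 bars on a
3×3 grid (3 rows, 3 columns, 2 diagonals; active 2.1 Hz), with a 4-pattern
subset (middle row, middle column, both diagonals).  Noisy probes add
uniform noise of half-width η·M/2 (interval config-exposed) to a pattern of
amplitude M = 10 Hz, floored at zero.  Input weights are initialized
uniformly in [0.001, 0.01]; behavior is insensitive to this interval since
multiplicative learning rescales it.

## Experiment configurations

The preset experiments pin per-run choices that the underlying description
leaves open.  The connectivity experiment uses the full 250-neuron scale.
Learned-network experiments use the 117E/30I analysis population.  The
homeostatic-convergence experiment runs with patterned input attached and a
target of 0.14 Hz (the low end of the plausible 0.14-0.68 Hz range): with
spontaneous drive alone, targets in this range demand recurrent
amplification so close to criticality that instantaneous-rate scaling
feedback limit-cycles at compressed time constants, whereas the
input-driven configuration converges smoothly.  The wave experiments use an
inhibitory target factor of 2; the discrete-pattern experiments use 4,
where the stronger shared inhibition is needed for assemblies to compete.
The selectivity experiment runs at a target of 0.4 Hz — at 0.68 Hz the
cap-limited gain regime broadens excitatory tuning and the population
selectivity contrast disappears.  These couplings between target rate,
inhibition strength and function are properties of this implementation at
its reduced scale, and all of the knobs are exposed in the run config.

## Analyses

Per-neuron gain is steady-state rate over feed-forward drive (undefined at
zero drive).  The network gain summarizing a learned WTA is the median
over hill positions of the *winning* excitatory neuron's gain — the winner
is always well-driven, so the ratio is meaningful, whereas the maximum
over all neurons diverges for neurons with negligible drive.  Response
similarity is the cosine of population rate vectors.  OSI uses
(R_pref − R_orth)/(R_pref + R_orth) with the preferred angle at the tuning
curve's maximum and orthogonal at half the ring — reproducing the [0, 1]
range with 0 for flat and 1 for single-angle curves.  REE (recursively
effective exertion) is presynaptic activity × connection weight; inhibitory
breakdowns are normalized to percentages.  The network-gain summary over ring
positions is the median by default (robust to the occasional weakly-driven
winner); the gain-versus-target comparison uses the mean, which resolves
ties the median produces when adjacent targets share winner clusters.  The
1-D ordering that exposes
the learned band minimizes Σ w_ij·|pos_i − pos_j| by simulated annealing
(only the energy matters, not the optimizer; an exhaustive search bounds it
on small instances).

## Problem sizes and what the tests show

The full-scale growth (250 neurons, 160 µm cube, ~3000 growth steps) runs
in well under a minute per seed and carries the connectivity statistics.
Learned-network experiments use a grown 80E/20I network (cube scaled to
keep density), 20 input populations, and a few hundred learning periods —
deliberately smaller and shorter than the original day-long simulations.
Synthetic stimuli are stylized hills and bars, not biological retinal
waves; passing tests therefore demonstrate the self-organization
mechanisms (homeostatic convergence, band formation, decorrelation,
selectivity contrasts, inhibition concentration) at reduced scale, not
quantitative biological realism of any individual arbor or tuning curve.

## Known limitations

Growth cones ignore mechanical interactions, so arbors can overlap freely;
connectivity statistics, not geometry, are the validated surface.  The
homeostatic phase under weak feed-forward input can enter slow
inflate/saturate cycles near criticality; the two-phase schedule with the
specification phase's long relaxations resolves this, but individual seeds
differ noticeably in their learned gain — quantitative gain comparisons
are made on medians across stimulus positions and should use several seeds.
The PSD (presynaptic-dependent) scaling variant and spiking dynamics are
out of scope.
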