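"""Two-phase learning on a grown network.

Couples the rate dynamics, the stimulus schedules and the plasticity rules
into the developmental sequence: a homeostatic phase in which every synapse
follows synaptic scaling while the network (optionally still growing) is
driven by spontaneous activity and, later, patterned input; then a
specification phase in which synapses onto excitatory neurons switch to the
BCM rule and the network learns the topology of its inputs.

Learning operates on the summed connection-weight matrix; because both
rules are linear in the synaptic weight this is exactly equivalent to
updating each synapse individually and summing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import NetworkWeights, W_MAX_SINGLE, apply_caps, steady_state
from .plasticity import ActivityAverage, HomeostasisParams, bcm_update, \
    rule_router, scaling_update, theta_update
from .stimuli import StimulusSchedule

__all__ = ["LearnState", "network_from_synapses", "run_phase", "respond"]

SPONT_INTERVAL = (0.0, 0.06)  # Hz, spontaneous activity per presentation


def network_from_synapses(synapses: np.ndarray, n_neurons: int) -> NetworkWeights:
    """Sum per-synapse weights into the signed connection-weight matrix."""
    w = np.zeros((n_neurons, n_neurons))
    n_syn = np.zeros((n_neurons, n_neurons), dtype=int)
    np.add.at(w, (synapses["post"], synapses["pre"]), synapses["sign"] * synapses["weight"])
    np.add.at(n_syn, (synapses["post"], synapses["pre"]), 1)
    return NetworkWeights(w=w, n_syn=n_syn)


@dataclass
class LearnState:
    """Mutable state of the learning stage.

    ``W`` are the recurrent connection weights (with synapse-count caps);
    ``W_in`` the non-negative feed-forward projection weights.  Input axons
    are not grown, so input projections carry no synapse count; they are
    treated as two-synapse connections and capped at ``cap_in`` = 0.2 (the
    same per-synapse maximum that governs grown connections).
    """

    W: NetworkWeights
    W_in: np.ndarray
    is_excitatory: np.ndarray
    params: HomeostasisParams
    cap_in: float = 0.2
    avg: ActivityAverage | None = None
    n_iter: int = 300
    dt: float = 0.1

    @property
    def n(self) -> int:
        return len(self.is_excitatory)

    def a_goal(self) -> np.ndarray:
        return self.params.a_goal(self.is_excitatory)


def respond(state: LearnState, x_in: np.ndarray, s: np.ndarray | float = 0.0,
            n_iter: int | None = None, dt: float | None = None):
    """Steady-state network rates for one input vector."""
    x = state.W_in @ np.asarray(x_in, float)
    st, conv = steady_state(state.W, x=x, s=s,
                            n_iter=n_iter or state.n_iter, dt=dt or state.dt)
    return st.r, x, conv


def _learning_step(state: LearnState, rates: np.ndarray, inputs: np.ndarray,
                   phase: str, variant: str, eta_scal: float, eta_bcm: float):
    """One learning step after a full stimulus period.

    ``rates`` is (n_presentations, n) network activity, ``inputs`` the
    matching (n_presentations, n_pops) input-population activity.
    """
    p = state.params
    a_goal = state.a_goal()
    a_bar = state.avg.a_bar
    use_bcm = rule_router(state.is_excitatory, phase, variant)

    # synaptic scaling rows (postsynaptic neurons not under BCM)
    sc = ~use_bcm
    if sc.any():
        state.W.w[sc] = scaling_update(state.W.w[sc], a_bar[sc], a_goal[sc],
                                       1.0 / eta_scal, 1.0)
        state.W_in[sc] = scaling_update(state.W_in[sc], a_bar[sc], a_goal[sc],
                                        1.0 / eta_scal, 1.0)
    if use_bcm.any():
        c = p.c(state.is_excitatory)[use_bcm]
        theta = c * state.avg.a_sq_bar[use_bcm]
        r_post = rates[:, use_bcm]
        state.W.w[use_bcm] = bcm_update(state.W.w[use_bcm], rates, r_post,
                                        theta, 1.0 / eta_bcm, 1.0)
        state.W_in[use_bcm] = bcm_update(state.W_in[use_bcm], inputs, r_post,
                                         theta, 1.0 / eta_bcm, 1.0)
    apply_caps(state.W)
    np.clip(state.W_in, 0.0, state.cap_in, out=state.W_in)


def run_phase(state: LearnState, schedule: StimulusSchedule, phase: str,
              n_periods: int, rng: np.random.Generator, variant: str = "default",
              eta_scal: float = 0.5, eta_bcm: float = 2.0,
              rate_log: list | None = None, growth_hook=None):
    """Run one developmental phase for ``n_periods`` stimulus periods.

    One learning step is applied after each full period (a sweep of the wave
    over all input populations, or one pass over all discrete patterns, with
    active/non-active alternation).  ``growth_hook(state, period)``, if
    given, is called after each period and may add synapses (the homeostatic
    phase runs while the network is still growing).  ``rate_log`` collects
    (mean excitatory rate, mean inhibitory rate, synapse count) per period.
    """
    n = state.n
    if state.avg is None:
        state.avg = ActivityAverage(n, max(schedule.n_per_period(), 10))
    for period in range(n_periods):
        rates, inputs = [], []
        for x_in, _active in schedule.period():
            s = rng.uniform(*SPONT_INTERVAL, size=n)
            r, _x, _conv = respond(state, x_in, s=s)
            state.avg.push(r)
            rates.append(r)
            inputs.append(x_in)
        rates = np.array(rates)
        inputs = np.array(inputs)
        if state.avg.warmed_up:
            _learning_step(state, rates, inputs, phase, variant, eta_scal, eta_bcm)
        if growth_hook is not None:
            growth_hook(state, period)
        if rate_log is not None:
            exc = state.is_excitatory
            rate_log.append((float(state.avg.a_bar[exc].mean()),
                             float(state.avg.a_bar[~exc].mean()),
                             int(state.W.n_syn.sum())))
    return state
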