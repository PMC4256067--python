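"""End-to-end developmental runs.

Orchestrates the full sequence under one config and one master seed:

1. GRN lineage expansion fixes the numbers of excitatory and inhibitory
   neurons.
2. Somata are placed uniformly in the cube and neurites grow.
3. **Homeostatic phase** — growth, synapse formation and synaptic scaling
   run concurrently: growth proceeds in epochs, newly formed synapses are
   summed into the connection-weight matrix at their initial weights, and a
   scaling step follows every stimulus period.  The patterned input layer is
   attached in the later stages of this phase; before that the network is
   driven by spontaneous activity alone.  The concurrency matters: synapses
   arriving while rates already hover at their targets are what leaves the
   converged network with a balanced mixture of excitation and inhibition.
4. **Specification phase** — synapses onto excitatory neurons switch to the
   BCM rule and the network learns the input topology.
5. Analyses run on the learned network.

Checkpoints at every stage boundary allow resuming; resuming reproduces the
same downstream results as an uninterrupted run with the same seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import grn
from .dynamics import NetworkWeights, apply_caps
from .learning import LearnState, network_from_synapses, run_phase
from .morphogenesis import (GrowthState, Somata, SYN_DTYPE, W_INIT_EXC,
                            W_INIT_INH, _KIND, cube_side_for_density,
                            form_synapses, place_somata)
from .plasticity import ActivityAverage, HomeostasisParams
from .stimuli import StimulusSchedule, bar_patterns, init_input_weights

__all__ = ["RunConfig", "DevelopmentalRun", "PRESETS", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a standard run needs; defaults follow the published values
    where one exists and the package's calibration elsewhere."""

    n_target: int = 250
    ei_ratio: float = 0.8
    use_lineage: bool = True          # derive counts from a simulated lineage
    cube_side: float | None = None    # None: choose for 61,000 neurons/mm^3
    density: float = 61_000.0
    growth_steps: int = 2500
    growth_epoch: int = 100           # growth steps between synapse updates
    input_attach_frac: float = 0.5    # fraction of growth before input attaches
    # stimuli
    stimulus_mode: str = "wave"       # wave | patterns | silent
    n_pops: int = 20
    grid: int = 3
    subset4: bool = False
    # plasticity
    a_goal_E: float = 0.4
    a_goal_I_factor: float = 2.0
    eta_scal: float = 0.5
    eta_bcm: float = 0.05
    # schedule lengths (periods)
    homeostatic_periods: int = 300    # after growth has finished
    specification_periods: int = 250
    periods_per_epoch: int = 8        # learning periods between growth epochs
    variant: str = "default"          # default | all-bcm
    # numerics
    n_iter: int = 200          # rate-relaxation iterations per presentation
    n_iter_spec: int = 1000    # longer relaxation during specification, so
                               # near-critical modes surface and BCM's sliding
                               # threshold can rein them in
    dt: float = 0.1
    master_seed: int = 0

    def pattern_set(self):
        return bar_patterns(self.grid, subset4=self.subset4)

    def input_count(self) -> int:
        """Number of input populations (= width of the input weight matrix)."""
        if self.stimulus_mode == "patterns":
            return self.grid * self.grid
        return self.n_pops

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(dataclasses.asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:16]


def save_config(cfg: RunConfig, path: str | Path):
    import yaml

    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)))


def load_config(path: str | Path) -> RunConfig:
    import yaml

    return RunConfig(**yaml.safe_load(Path(path).read_text()))


# named experiment presets (reduced scale for desk-size runs); the learned
# network uses the 117E/30I analysis population
PRESETS = {
    "connectivity": RunConfig(n_target=250, use_lineage=False),
    "homeostasis": RunConfig(n_target=100, use_lineage=False, a_goal_E=0.14,
                             homeostatic_periods=500),
    "wta_waves": RunConfig(n_target=147, use_lineage=False, a_goal_E=0.68,
                           homeostatic_periods=150),
    "clustering_8patterns": RunConfig(n_target=100, use_lineage=False,
                                      stimulus_mode="patterns", a_goal_E=0.55,
                                      a_goal_I_factor=4.0,
                                      homeostatic_periods=150),
    "clustering_4patterns": RunConfig(n_target=100, use_lineage=False,
                                      stimulus_mode="patterns", subset4=True,
                                      a_goal_E=0.55, a_goal_I_factor=4.0,
                                      homeostatic_periods=150),
    "competition": RunConfig(n_target=100, use_lineage=False,
                             stimulus_mode="patterns", subset4=True,
                             a_goal_E=0.55, a_goal_I_factor=4.0,
                             homeostatic_periods=150),
    "osi": RunConfig(n_target=147, use_lineage=False, a_goal_E=0.4,
                     homeostatic_periods=150),
    "osi_allbcm": RunConfig(n_target=147, use_lineage=False, a_goal_E=0.4,
                            variant="all-bcm", homeostatic_periods=150),
    "ree": RunConfig(n_target=147, use_lineage=False, a_goal_E=0.68,
                     homeostatic_periods=150),
}


def _incremental_synapses(gs: GrowthState, prev_seg_n: int) -> np.ndarray:
    """Synapses involving segments created at or after ``prev_seg_n``.

    Complements an earlier full scan: returns (new bouton x any spine) plus
    (old bouton x new spine) pairs, deduplicated, no autapses.
    """
    from scipy.spatial import cKDTree

    n = gs.seg.n
    alive = gs.seg.alive[:n]
    kind = gs.seg.kind[:n]
    neuron = gs.seg.neuron[:n]
    mid = (gs.seg.prox[:n] + gs.seg.dist[:n]) / 2.0
    is_new = np.arange(n) >= prev_seg_n
    ax = alive & (kind == _KIND["axon"])
    de = alive & (kind == _KIND["dendrite"])
    pairs = set()

    def collect(b_ids, s_ids):
        if not len(b_ids) or not len(s_ids):
            return
        tb = cKDTree(mid[b_ids])
        ts = cKDTree(mid[s_ids])
        for bi, lst in enumerate(tb.query_ball_tree(ts, 2.0)):
            gb = b_ids[bi]
            for si in lst:
                gd = s_ids[si]
                if neuron[gb] != neuron[gd]:
                    pairs.add((int(gb), int(gd)))

    collect(np.flatnonzero(ax & is_new), np.flatnonzero(de))
    collect(np.flatnonzero(ax & ~is_new), np.flatnonzero(de & is_new))
    res = np.zeros(len(pairs), dtype=SYN_DTYPE)
    if pairs:
        arr = np.array(sorted(pairs))
        res["pre_seg"], res["post_seg"] = arr[:, 0], arr[:, 1]
        res["pre"] = neuron[arr[:, 0]]
        res["post"] = neuron[arr[:, 1]]
        pos = (mid[arr[:, 0]] + mid[arr[:, 1]]) / 2.0
        res["x"], res["y"], res["z"] = pos.T
        pre_exc = gs.somata.is_excitatory[res["pre"]]
        res["sign"] = np.where(pre_exc, 1, -1)
        res["weight"] = np.where(pre_exc, W_INIT_EXC, W_INIT_INH)
        gs.mark_synapse_segments(np.concatenate([arr[:, 0], arr[:, 1]]))
    return res


class DevelopmentalRun:
    """A full run with checkpointing at stage boundaries."""

    STAGES = ("lineage", "morphology", "homeostatic_done", "learned")

    def __init__(self, cfg: RunConfig, checkpoint_dir: str | Path | None = None):
        self.cfg = cfg
        self.ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
        seq = np.random.SeedSequence(cfg.master_seed)
        kids = seq.spawn(4)
        self.rng_lineage = np.random.default_rng(kids[0])
        self.rng_growth = np.random.default_rng(kids[1])
        self.rng_learn = np.random.default_rng(kids[2])
        self.rng_place = np.random.default_rng(kids[3])
        self.report: dict = {}
        self.rate_log: list = []
        self.synapses: np.ndarray | None = None

    # -- stage 1: lineage ---------------------------------------------
    def stage_lineage(self):
        cfg = self.cfg
        if cfg.use_lineage:
            fate = grn.division_probabilities(cfg.n_target, cfg.ei_ratio)
            params = grn.GRNParams()
            params.alpha1 = grn.calibrate_alpha1(fate.n1, params.cell_cycle_time, params)
            tree = grn.simulate_lineage(params, fate, int(self.rng_lineage.integers(2**31)))
            n_e, n_i = tree.counts()
            self.lineage = tree
        else:
            n_e = round(cfg.n_target * cfg.ei_ratio)
            n_i = cfg.n_target - n_e
            self.lineage = None
        self.n_exc, self.n_inh = n_e, n_i
        self.report["lineage"] = {"n_exc": n_e, "n_inh": n_i}
        self._checkpoint("lineage")
        return self

    # -- stages 2+3: growth with concurrent homeostasis ---------------
    def stage_develop(self):
        """Grow morphology while running the homeostatic phase."""
        cfg = self.cfg
        side = cfg.cube_side or cube_side_for_density(self.n_exc + self.n_inh, cfg.density)
        self.somata = place_somata(self.n_exc, self.n_inh, side, self.rng_place)
        n = self.somata.n
        gs = GrowthState(self.somata, seed=self.rng_growth)
        self.gs = gs

        params = HomeostasisParams(a_goal_E=cfg.a_goal_E,
                                   a_goal_I_factor=cfg.a_goal_I_factor)
        n_inputs = cfg.input_count()
        W = NetworkWeights(w=np.zeros((n, n)), n_syn=np.zeros((n, n), int))
        self.state = LearnState(W=W, W_in=init_input_weights(n_inputs, n, self.rng_learn),
                                is_excitatory=self.somata.is_excitatory,
                                params=params, n_iter=cfg.n_iter, dt=cfg.dt)
        self.schedule = self._make_schedule()
        silent = StimulusSchedule("silent", n_inputs, self.rng_learn)

        syn_batches = []
        prev_seg = 0
        attach_at = int(cfg.growth_steps * cfg.input_attach_frac)
        steps_done = 0
        self.state.avg = ActivityAverage(n, 10)
        input_attached = False
        while steps_done < cfg.growth_steps and np.any(gs.c_state != 2):
            gs.run(max_steps=cfg.growth_epoch)
            steps_done += cfg.growth_epoch
            batch = _incremental_synapses(gs, prev_seg)
            prev_seg = gs.seg.n
            if len(batch):
                syn_batches.append(batch)
                np.add.at(W.w, (batch["post"], batch["pre"]),
                          batch["sign"] * batch["weight"])
                np.add.at(W.n_syn, (batch["post"], batch["pre"]), 1)
                apply_caps(W)
            if not input_attached and steps_done >= attach_at:
                input_attached = True
                self.state.avg = ActivityAverage(n, self.schedule.n_per_period())
            sched = self.schedule if input_attached else silent
            periods = cfg.periods_per_epoch
            run_phase(self.state, sched, "homeostatic", periods, self.rng_learn,
                      eta_scal=cfg.eta_scal, rate_log=self.rate_log)
        self.synapses = np.concatenate(syn_batches) if syn_batches else np.zeros(0, SYN_DTYPE)
        self.report["morphology"] = {
            "n_segments": int(gs.seg.alive[: gs.seg.n].sum()),
            "n_synapses": int(len(self.synapses)),
            "cube_side": side,
        }
        self._checkpoint("morphology")

        # homeostatic tail: growth finished, input attached, scaling continues
        run_phase(self.state, self.schedule, "homeostatic",
                  cfg.homeostatic_periods, self.rng_learn,
                  eta_scal=cfg.eta_scal, rate_log=self.rate_log)
        exc = self.somata.is_excitatory
        self.report["homeostasis"] = {
            "mean_rate_exc": float(self.state.avg.a_bar[exc].mean()),
            "mean_rate_inh": float(self.state.avg.a_bar[~exc].mean()),
            "target_exc": params.a_goal_E,
            "target_inh": params.a_goal_I,
        }
        self._checkpoint("homeostatic_done")
        return self

    def _make_schedule(self) -> StimulusSchedule:
        cfg = self.cfg
        if cfg.stimulus_mode == "wave":
            return StimulusSchedule("wave", cfg.n_pops, self.rng_learn)
        if cfg.stimulus_mode == "silent":
            return StimulusSchedule("silent", cfg.n_pops, self.rng_learn)
        pats = cfg.pattern_set()
        return StimulusSchedule("patterns", pats.shape[1], self.rng_learn,
                                patterns=pats)

    # -- stage 4: specification ---------------------------------------
    def stage_specify(self):
        cfg = self.cfg
        # neurons without inhibitory input cannot take part in competitive
        # learning and are excluded from the analyzed population
        inh_in = np.abs(self.state.W.w[:, ~self.somata.is_excitatory]).sum(1)
        self.excluded = np.flatnonzero(inh_in == 0)
        self.report["excluded_no_inhibition"] = [int(i) for i in self.excluded]
        self.state.n_iter = cfg.n_iter_spec
        run_phase(self.state, self.schedule, "specification",
                  cfg.specification_periods, self.rng_learn,
                  eta_scal=cfg.eta_scal, eta_bcm=cfg.eta_bcm,
                  variant=cfg.variant, rate_log=self.rate_log)
        self._checkpoint("learned")
        return self

    def run_standard(self):
        return self.stage_lineage().stage_develop().stage_specify()

    # -- checkpointing -------------------------------------------------
    def _checkpoint(self, stage: str):
        if self.ckpt_dir is None:
            return
        import h5py

        self.ckpt_dir.mkdir(parents=True, exist_ok=True)
        path = self.ckpt_dir / f"{stage}.h5"
        with h5py.File(path, "w") as f:
            f.attrs["stage"] = stage
            f.attrs["config_hash"] = self.cfg.hash()
            f.attrs["config_json"] = json.dumps(dataclasses.asdict(self.cfg))
            if stage == "lineage":
                f.attrs["n_exc"] = self.n_exc
                f.attrs["n_inh"] = self.n_inh
                if self.lineage is not None:
                    f.attrs["lineage_json"] = self.lineage.to_json()
            else:
                f.create_dataset("positions", data=self.somata.positions)
                f.create_dataset("is_excitatory", data=self.somata.is_excitatory)
                f.create_dataset("W", data=self.state.W.w)
                f.create_dataset("n_syn", data=self.state.W.n_syn)
                f.create_dataset("W_in", data=self.state.W_in)
                if self.synapses is not None:
                    for name in self.synapses.dtype.names:
                        f.create_dataset(f"synapses/{name}", data=self.synapses[name])

    @staticmethod
    def load_network(path: str | Path):
        """Load (W: NetworkWeights, W_in, is_excitatory, positions) from a checkpoint."""
        import h5py

        with h5py.File(path, "r") as f:
            W = NetworkWeights(w=f["W"][:], n_syn=f["n_syn"][:])
            return W, f["W_in"][:], f["is_excitatory"][:].astype(bool), f["positions"][:]

    def resume_from(self, path: str | Path, override_config: bool = False):
        """Check a checkpoint's config hash and load its network state."""
        import h5py

        with h5py.File(path, "r") as f:
            if f.attrs["config_hash"] != self.cfg.hash() and not override_config:
                raise ValueError("checkpoint config hash does not match; "
                                 "pass override_config=True to proceed")
        W, W_in, is_exc, pos = self.load_network(path)
        self.somata = Somata(positions=pos, is_excitatory=is_exc)
        params = HomeostasisParams(a_goal_E=self.cfg.a_goal_E,
                                   a_goal_I_factor=self.cfg.a_goal_I_factor)
        self.state = LearnState(W=W, W_in=W_in, is_excitatory=is_exc,
                                params=params, n_iter=self.cfg.n_iter, dt=self.cfg.dt)
        self.schedule = self._make_schedule()
        return self
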