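"""Shared fixtures: developmental runs reused across acceptance tests.

The learned-network runs are the expensive fixtures (a few minutes each);
they are session-scoped and every test that can share one does.  Seeds are
fixed constants so the suite is reproducible end to end.
"""

import copy
import dataclasses

import numpy as np
import pytest

from devwta.learning import run_phase
from devwta.pipeline import DevelopmentalRun, PRESETS, RunConfig


def _wave_config(a_goal_E: float, seed: int) -> RunConfig:
    return RunConfig(n_target=147, use_lineage=False, a_goal_E=a_goal_E,
                     master_seed=seed, homeostatic_periods=150,
                     specification_periods=250)


def _run_with_homeo_copy(cfg: RunConfig):
    run = DevelopmentalRun(cfg)
    run.stage_lineage().stage_develop()
    run.homeo_state = copy.deepcopy(run.state)
    run.stage_specify()
    return run


@pytest.fixture(scope="session")
def wave_run_068():
    """Learned WTA network at the highest homeostatic target (0.68 Hz)."""
    return _run_with_homeo_copy(_wave_config(0.68, 0))


@pytest.fixture(scope="session")
def wave_run_055():
    return _run_with_homeo_copy(_wave_config(0.55, 0))


@pytest.fixture(scope="session")
def wave_run_040():
    """Learned network at target 0.4 Hz; also the basis of the selectivity
    experiments (its homeostatic state is re-specified for the all-BCM
    control)."""
    return _run_with_homeo_copy(_wave_config(0.4, 0))


@pytest.fixture(scope="session")
def allbcm_state(wave_run_040):
    """Specification re-run with BCM routed to every synapse."""
    base = wave_run_040
    state = copy.deepcopy(base.homeo_state)
    state.n_iter = base.cfg.n_iter_spec
    rng = np.random.default_rng(12345)
    run_phase(state, base.schedule, "specification",
              base.cfg.specification_periods, rng,
              eta_scal=base.cfg.eta_scal, eta_bcm=base.cfg.eta_bcm,
              variant="all-bcm")
    return state, base.somata.is_excitatory


@pytest.fixture(scope="session")
def patterns8_run():
    cfg = dataclasses.replace(PRESETS["clustering_8patterns"], master_seed=0)
    run = DevelopmentalRun(cfg)
    run.stage_lineage().stage_develop()
    run.pre_spec_state = copy.deepcopy(run.state)
    run.stage_specify()
    return run


@pytest.fixture(scope="session")
def patterns4_run():
    cfg = dataclasses.replace(PRESETS["clustering_4patterns"], master_seed=0)
    return DevelopmentalRun(cfg).run_standard()


@pytest.fixture(scope="session")
def homeostasis_run():
    cfg = dataclasses.replace(PRESETS["homeostasis"], master_seed=0)
    run = DevelopmentalRun(cfg)
    return run.stage_lineage().stage_develop()
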