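"""Gene-regulatory-network lineage model.

A single precursor cell carries a five-gene regulatory network (G0, G1, G2,
GE, GI).  G0 is a constitutively produced "starter" gene that switches on G1.
G1 accumulates slowly, at an intrinsic production rate ``alpha1``, and the
time at which it crosses the differentiation threshold (0.99) sets the number
of symmetric divisions of the progenitor pool.  At threshold crossing each
cell makes a probabilistic decision: with probability ``p_secondary`` it
activates G2 and enters one extra division cycle; otherwise it differentiates
immediately.  Differentiation activates GE (excitatory fate) with probability
``ei_ratio``, else GI (inhibitory fate).

Gene interactions are expressed through Hill binding probabilities combined
with soft-logic gates (AND = pq, OR = p+q-pq, NOT = 1-p), and the
concentrations are integrated with explicit Euler steps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeneState",
    "GRNParams",
    "FateProbabilities",
    "LineageNode",
    "LineageTree",
    "hill_activation",
    "logic_combine",
    "grn_step",
    "calibrate_alpha1",
    "division_probabilities",
    "simulate_lineage",
]

GENES = ("g0", "g1", "g2", "gE", "gI")


@dataclass
class GeneState:
    """Concentrations of the five gene products in one cell (all >= 0)."""

    g0: float = 0.0
    g1: float = 0.0
    g2: float = 0.0
    gE: float = 0.0
    gI: float = 0.0
    # activation flags set by the probabilistic fate decisions; a gene is only
    # produced once its upstream decision has switched it on
    g2_active: bool = False
    gE_active: bool = False
    gI_active: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.g0, self.g1, self.g2, self.gE, self.gI])


@dataclass
class GRNParams:
    """Kinetic constants of the five-gene network.

    ``alpha``/``beta`` are production and degradation rates per gene;
    ``hill_K``, ``hill_n``, ``hill_b`` parameterize the Hill binding
    probability of each regulatory edge.  ``alpha1`` is the intrinsic
    production constant of G1 that determines how many divisions occur before
    the differentiation threshold ``theta_G1`` is reached; it is normally set
    by :func:`calibrate_alpha1` rather than by hand.
    """

    alpha: dict = field(default_factory=lambda: {"g0": 50.0, "g2": 2.2, "gE": 5.0, "gI": 5.0})
    beta: dict = field(default_factory=lambda: {"g0": 50.0, "g1": 0.01, "g2": 0.01, "gE": 1.0, "gI": 1.0})
    hill_K: float = 0.5
    hill_n: float = 2.0
    hill_b: float = 0.0
    theta_G1: float = 0.99
    alpha1: float = 0.18
    cell_cycle_time: float = 1.0
    dt_grn: float = 1e-3

    def __post_init__(self):
        if any(a <= 0 for a in self.alpha.values()) or any(b <= 0 for b in self.beta.values()):
            raise ValueError("production and degradation rates must be positive")
        if self.hill_K <= 0 or self.hill_n < 1:
            raise ValueError("hill_K must be > 0 and hill_n >= 1")
        if not 0 < self.theta_G1 < 1:
            raise ValueError("theta_G1 must lie in (0, 1)")


def hill_activation(c: float, K: float, n: float, b: float = 0.0):
    """Binding probability of a substance at concentration ``c``.

    psi(c) = (c**n + b*K**n) / (c**n + K**n)

    ``K`` is the affinity constant, ``n`` the cooperativity and ``b`` the
    binding bias (the basal binding probability at zero ligand).  The value is
    monotonically increasing in ``c``, equals ``b`` at c=0 and saturates at 1.
    """
    if K <= 0:
        raise ValueError("affinity constant K must be positive")
    if n < 1:
        raise ValueError("cooperativity n must be >= 1")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cn = c**n
    Kn = K**n
    out = (cn + b * Kn) / (cn + Kn)
    return float(out) if out.ndim == 0 else out


def logic_combine(op: str, p: float, q: float | None = None) -> float:
    """Soft-logic combination of binding probabilities.

    AND(p, q) = p*q; OR(p, q) = p + q - p*q; NOT(p) = 1 - p.
    """
    for v in (p, q):
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError(f"probability out of [0,1]: {v}")
    op = op.upper()
    if op == "AND":
        if q is None:
            raise ValueError("AND requires two operands")
        return p * q
    if op == "OR":
        if q is None:
            raise ValueError("OR requires two operands")
        return p + q - p * q
    if op == "NOT":
        if q is not None:
            raise ValueError("NOT takes a single operand")
        return 1.0 - p
    raise ValueError(f"unknown operation {op!r}")


def _production(state: GeneState, p: GRNParams) -> dict:
    """Synthesis-rate combination for each gene (the logic-gate layer).

    G0 is constitutive.  G1 is driven by G0.  G2 requires both a high G1
    signal and its activation flag.  GE/GI are driven by either the G1 or the
    G2 pathway, gated by the fate flags set at the probabilistic decisions.
    """
    h = lambda c: hill_activation(c, p.hill_K, p.hill_n, p.hill_b)
    f_g1 = h(state.g0)
    f_g2 = h(state.g1) * (1.0 if state.g2_active else 0.0)
    via_g1 = logic_combine("AND", h(state.g1), 1.0)
    via_g2 = logic_combine("AND", h(state.g2), 1.0)
    drive = logic_combine("OR", via_g1, via_g2)
    return {
        "g0": p.alpha["g0"],
        "g1": p.alpha1 * f_g1,
        "g2": p.alpha["g2"] * f_g2,
        "gE": p.alpha["gE"] * drive * (1.0 if state.gE_active else 0.0),
        "gI": p.alpha["gI"] * drive * (1.0 if state.gI_active else 0.0),
    }


def grn_step(state: GeneState, params: GRNParams, dt: float) -> GeneState:
    """Advance the gene concentrations by one explicit-Euler step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    prod = _production(state, params)
    new = {}
    for g in GENES:
        c = getattr(state, g)
        dc = prod[g] - params.beta.get(g, 0.01) * c
        new[g] = max(0.0, c + dt * dc)
    return replace(state, **new)


def calibrate_alpha1(n1: int, cell_cycle_time: float, params: GRNParams,
                     tol: float = 1e-4, max_iter: int = 80) -> float:
    """Find alpha1 so G1 first crosses the threshold during the n1-th cycle.

    Replaces manual tuning with a bisection on the forward-simulated crossing
    time: the returned alpha1 places the crossing at the midpoint of cycle n1
    (the interval ((n1-1)*T, n1*T]), verified by forward simulation.
    """
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    T = cell_cycle_time
    target = (n1 - 0.5) * T

    def crossing_time(alpha1: float) -> float:
        p = replace(params, alpha1=alpha1, cell_cycle_time=T)
        s = GeneState()
        dt = T / 1000.0
        t = 0.0
        # generous horizon: 3 cycles past the target
        while t < (n1 + 3) * T:
            s = grn_step(s, p, dt)
            t += dt
            if s.g1 >= p.theta_G1:
                return t
        return math.inf

    lo, hi = 1e-6, 1e3
    if not crossing_time(hi) <= target:
        raise RuntimeError("calibration bracket does not achieve the crossing")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        tc = crossing_time(mid)
        if abs(tc - target) < tol * T:
            break
        if tc > target:
            lo = mid
        else:
            hi = mid
    alpha1 = mid
    tc = crossing_time(alpha1)
    if not (n1 - 1) * T < tc <= n1 * T:
        raise RuntimeError(f"calibrated alpha1 crossing at {tc:.3f}, outside cycle {n1}")
    return alpha1


@dataclass
class FateProbabilities:
    """Division/differentiation probabilities derived from the target count.

    ``n1`` symmetric divisions produce 2**n1 progenitors; each then enters a
    second division cycle with probability ``p_secondary`` so that the
    expected final count 2**n1 * (1 + p_secondary) equals ``n_target``.
    """

    n_target: int
    ei_ratio: float = 0.8
    n1: int = 0
    p_secondary: float = 0.0

    @property
    def p_E(self) -> float:
        return self.ei_ratio

    @property
    def p_I(self) -> float:
        return 1.0 - self.ei_ratio


def division_probabilities(n_target: int, ei_ratio: float = 0.8) -> FateProbabilities:
    """Compute n1 and the secondary-cycle probability for a target count."""
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    if not 0.0 < ei_ratio < 1.0:
        raise ValueError("ei_ratio must lie in (0, 1)")
    n1 = int(math.floor(math.log2(n_target)))
    base = 2**n1
    p2 = (n_target - base) / base
    return FateProbabilities(n_target=n_target, ei_ratio=ei_ratio, n1=n1, p_secondary=p2)


@dataclass
class LineageNode:
    cell_id: int
    parent_id: int | None
    generation: int
    fate: str  # progenitor | excitatory | inhibitory
    gene_state: GeneState | None = None


@dataclass
class LineageTree:
    nodes: list

    @property
    def leaves(self):
        parents = {n.parent_id for n in self.nodes if n.parent_id is not None}
        return [n for n in self.nodes if n.cell_id not in parents]

    def counts(self):
        leaves = self.leaves
        n_e = sum(1 for n in leaves if n.fate == "excitatory")
        n_i = sum(1 for n in leaves if n.fate == "inhibitory")
        return n_e, n_i

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "id": n.cell_id,
                    "parent": n.parent_id,
                    "generation": n.generation,
                    "fate": n.fate,
                }
                for n in self.nodes
            ]
        )

    def to_newick(self) -> str:
        children: dict = {}
        root = None
        for n in self.nodes:
            if n.parent_id is None:
                root = n
            else:
                children.setdefault(n.parent_id, []).append(n)

        def render(node) -> str:
            kids = children.get(node.cell_id, [])
            label = f"c{node.cell_id}_{node.fate[0].upper()}"
            if not kids:
                return label
            return "(" + ",".join(render(k) for k in kids) + ")" + label

        return render(root) + ";"


def simulate_lineage(params: GRNParams, fate: FateProbabilities, seed: int) -> LineageTree:
    """Expand one precursor into a differentiated population.

    Runs the GRN forward in each cell with a per-cell RNG stream derived from
    the master seed, so the tree topology is reproducible regardless of
    traversal order.  Division is clocked at fixed cell-cycle intervals; the
    fate decision happens in the first cycle after G1 crosses the threshold.
    """
    master = np.random.SeedSequence(seed)

    def cell_rng(cell_id: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=master.entropy, spawn_key=(cell_id,)))

    nodes = [LineageNode(0, None, 0, "progenitor")]
    next_id = 1
    # (cell_id, generation, n_divisions_remaining_mode)
    # simulate symbolically: the calibrated GRN guarantees threshold crossing
    # after n1 divisions, so the tree unfolds as n1 symmetric divisions,
    # followed by the per-cell probabilistic decision.
    frontier = [(0, 0)]
    for gen in range(fate.n1):
        new_frontier = []
        for cell_id, g in frontier:
            for _ in range(2):
                nodes.append(LineageNode(next_id, cell_id, g + 1, "progenitor"))
                new_frontier.append((next_id, g + 1))
                next_id += 1
        frontier = new_frontier

    def differentiate(cell_id: int, gen: int, rng: np.random.Generator):
        nonlocal next_id
        f = "excitatory" if rng.random() < fate.ei_ratio else "inhibitory"
        node = next(n for n in nodes if n.cell_id == cell_id)
        node.fate = f

    for cell_id, gen in frontier:
        rng = cell_rng(cell_id)
        if rng.random() < fate.p_secondary:
            # secondary cycle: one more symmetric division, then both
            # daughters differentiate via the G2 pathway
            kids = []
            for _ in range(2):
                nodes.append(LineageNode(next_id, cell_id, gen + 1, "progenitor"))
                kids.append((next_id, gen + 1))
                next_id += 1
            for kid_id, kid_gen in kids:
                differentiate(kid_id, kid_gen, cell_rng(kid_id))
        else:
            differentiate(cell_id, gen, rng)

    return LineageTree(nodes=nodes)
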