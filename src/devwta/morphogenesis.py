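"""3D neurite outgrowth and synapse formation.

Somata are placed uniformly at random in a cube.  Each neuron sprouts one
axon and three dendrites, grown by growth-cone agents that advance in
discrete steps: the new direction is a weighted sum of the previous
direction (weight 0.75) and a random unit perturbation (0.25), the neurite
diameter tapers with every move and every bifurcation, and outgrowth stops
when the diameter falls below the type-specific minimum.  Axons additionally
read a diffusible substance secreted by somata of the *opposite* cell class
(excitatory axons seek inhibitory somata and vice versa): they retract when
the sensed concentration drops below a low threshold and resume elongation
once it exceeds a higher one, which confines axonal arbors to regions
containing potential targets.  The substance field is the analytic
steady-state of diffusion with first-order degradation (a screened-Poisson
point-source kernel); somata are static sources, so the field never changes
during growth and can be pre-tabulated on a grid for speed.

Boutons and spines sit at the midpoints of the discretized axonal and
dendritic segments; a synapse forms for every complementary bouton-spine
pair closer than 2 um that does not belong to a single neuron (no autapses).
Segments that carry a synapse anchor the neurite: retraction never removes
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TABLE_GROWTH_PARAMS",
    "GrowthParams",
    "SubstanceField",
    "Somata",
    "place_somata",
    "concentration_at",
    "GrowthState",
    "grow_network",
    "form_synapses",
    "connectivity_stats",
    "brute_force_synapses",
    "export_swc",
]

SOMA_DIAMETER = 8.0     # um
NU = 7.0                # neurite discretization size, um
SYNAPSE_RADIUS = 2.0    # um, bouton-spine proximity criterion
DIFFUSION_D = 50.0
DEGRADATION_K = 5.0
W_INIT_EXC = 0.001
W_INIT_INH = 0.01
DENSITY_RANGE = (40_000.0, 86_900.0)  # neurons per mm^3


@dataclass
class GrowthParams:
    """Growth-cone parameters for one (cell class, neurite kind) pair."""

    d_min: float
    dd_move: float
    dd_bif: float
    p_b0: float
    p_bc: float
    v_grow: float = 100.0
    v_retract: float = 5.0
    e_low: float | None = None    # retraction trigger (axons only)
    e_high: float | None = None   # retraction stop (axons only)
    w_prev: float = 0.75
    w_rand: float = 0.25
    nu: float = NU
    d_init: float = 1.0

    def __post_init__(self):
        if self.e_low is not None and self.e_high is not None and self.e_low >= self.e_high:
            raise ValueError("retraction-trigger threshold must lie below the stop threshold")
        if abs(self.w_prev + self.w_rand - 1.0) > 1e-12:
            raise ValueError("direction weights must sum to 1")


# per-(cell class, neurite kind) growth constants; initial diameters are the
# package's calibration of arbor size (they are not tabulated constants) and
# set the total axonal/dendritic path lengths that reproduce the observed
# connectivity statistics.
TABLE_GROWTH_PARAMS = {
    ("excitatory", "axon"): GrowthParams(
        d_min=0.2, dd_move=0.004, dd_bif=0.12, p_b0=0.05, p_bc=0.005,
        e_low=1e-8, e_high=0.036, d_init=2.45),
    ("inhibitory", "axon"): GrowthParams(
        d_min=0.2, dd_move=0.012, dd_bif=0.105, p_b0=0.08, p_bc=0.05,
        e_low=1e-8, e_high=0.036, d_init=1.56),
    ("excitatory", "dendrite"): GrowthParams(
        d_min=0.3, dd_move=0.02, dd_bif=0.14, p_b0=0.04, p_bc=0.0,
        v_retract=0.0, d_init=2.4),
    ("inhibitory", "dendrite"): GrowthParams(
        d_min=0.3, dd_move=0.042, dd_bif=0.12, p_b0=0.05, p_bc=0.0,
        v_retract=0.0, d_init=2.4),
}


@dataclass
class Somata:
    positions: np.ndarray           # (n, 3) um
    is_excitatory: np.ndarray       # (n,) bool
    diameter: float = SOMA_DIAMETER
    cube_side: float = 160.0

    @property
    def n(self) -> int:
        return len(self.positions)

    def density_per_mm3(self) -> float:
        return self.n / (self.cube_side / 1000.0) ** 3


def place_somata(n_exc: int, n_inh: int, cube_side: float,
                 rng: np.random.Generator) -> Somata:
    """Uniform i.i.d. soma positions inside the bounding cube.

    Warns (does not fail) if the resulting density falls outside the
    biologically observed 40,000-86,900 per mm^3 range.
    """
    if n_exc <= 0 or n_inh < 0 or cube_side <= 0:
        raise ValueError("counts and cube side must be positive")
    n = n_exc + n_inh
    pos = rng.uniform(0.0, cube_side, size=(n, 3))
    is_exc = np.zeros(n, bool)
    is_exc[:n_exc] = True
    s = Somata(positions=pos, is_excitatory=is_exc, cube_side=cube_side)
    d = s.density_per_mm3()
    if not DENSITY_RANGE[0] <= d <= DENSITY_RANGE[1]:
        import warnings

        warnings.warn(f"soma density {d:.0f}/mm^3 outside the biological range {DENSITY_RANGE}")
    return s


def cube_side_for_density(n: int, density: float = 61_000.0) -> float:
    """Cube side (um) that places n neurons at the given density per mm^3."""
    return 1000.0 * (n / density) ** (1.0 / 3.0)


def calibrate_secretion_rate(e_high: float = 0.036, r_ref: float = 20.0,
                             D: float = DIFFUSION_D, k: float = DEGRADATION_K) -> float:
    """Secretion rate Q such that one source yields C(r_ref) = e_high.

    Makes the tabulated retraction thresholds operative at the scale of
    inter-soma distances.
    """
    lam = np.sqrt(k / D)
    return e_high * 4.0 * np.pi * D * r_ref / np.exp(-lam * r_ref)


@dataclass
class SubstanceField:
    """Steady-state concentration field of a somatically secreted substance.

    Each source contributes Q/(4 pi D r) * exp(-r*sqrt(k/D)); the divergence
    at r -> 0 is capped at the value on the soma surface.
    """

    sources: np.ndarray             # (m, 3)
    Q: float
    D: float = DIFFUSION_D
    k: float = DEGRADATION_K
    r_cap: float = SOMA_DIAMETER / 2.0


def concentration_at(points: np.ndarray, fld: SubstanceField) -> np.ndarray:
    """Total concentration at one or more points (exact, additive over sources)."""
    pts = np.atleast_2d(np.asarray(points, float))
    if len(fld.sources) == 0:
        out = np.zeros(len(pts))
        return out if np.asarray(points).ndim > 1 else float(out[0])
    d = np.sqrt(((pts[:, None, :] - fld.sources[None, :, :]) ** 2).sum(-1))
    d = np.maximum(d, fld.r_cap)
    lam = np.sqrt(fld.k / fld.D)
    c = (fld.Q / (4.0 * np.pi * fld.D * d)) * np.exp(-lam * d)
    out = c.sum(axis=1)
    return out if np.asarray(points).ndim > 1 else float(out[0])


class _GriddedField:
    """Trilinear interpolation of a static SubstanceField on a lattice.

    The lattice extends ``margin`` um beyond the cube on every side; points
    outside it read zero concentration (well below the retraction trigger).
    """

    def __init__(self, fld: SubstanceField, cube_side: float,
                 margin: float = 60.0, spacing: float = 4.0):
        self.origin = -margin
        self.spacing = spacing
        n = int(np.ceil((cube_side + 2 * margin) / spacing)) + 1
        ax = self.origin + spacing * np.arange(n)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        # evaluate in chunks to bound memory (pts x sources pair matrix)
        vals = np.empty(len(pts))
        chunk = max(1000, 20_000_000 // max(len(fld.sources), 1))
        for lo in range(0, len(pts), chunk):
            vals[lo:lo + chunk] = concentration_at(pts[lo:lo + chunk], fld)
        self.grid = vals.reshape(n, n, n)
        self.n = n

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        f = (np.asarray(pts) - self.origin) / self.spacing
        i = np.floor(f).astype(int)
        inside = np.all((i >= 0) & (i < self.n - 1), axis=1)
        out = np.zeros(len(f))
        if inside.any():
            ii = i[inside]
            t = f[inside] - ii
            g = self.grid
            x, y, z = ii[:, 0], ii[:, 1], ii[:, 2]
            tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
            c = (g[x, y, z] * (1 - tx) * (1 - ty) * (1 - tz)
                 + g[x + 1, y, z] * tx * (1 - ty) * (1 - tz)
                 + g[x, y + 1, z] * (1 - tx) * ty * (1 - tz)
                 + g[x, y, z + 1] * (1 - tx) * (1 - ty) * tz
                 + g[x + 1, y + 1, z] * tx * ty * (1 - tz)
                 + g[x + 1, y, z + 1] * tx * (1 - ty) * tz
                 + g[x, y + 1, z + 1] * (1 - tx) * ty * tz
                 + g[x + 1, y + 1, z + 1] * tx * ty * tz)
            out[inside] = c
        return out


ELONGATING, RETRACTING, STOPPED = 0, 1, 2
STOP_NONE, STOP_TAPER, STOP_SOMA, STOP_ANCHOR = 0, 1, 2, 3
_KIND = {"axon": 0, "dendrite": 1}


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class _SegStore:
    """Append-friendly segment arrays with amortized growth."""

    FIELDS = ("neuron", "kind", "parent")

    def __init__(self, cap: int = 1024):
        self.n = 0
        self.neuron = np.empty(cap, np.int32)
        self.kind = np.empty(cap, np.int8)
        self.parent = np.empty(cap, np.int64)
        self.prox = np.empty((cap, 3))
        self.dist = np.empty((cap, 3))
        self.diam = np.empty(cap)
        self.alive = np.empty(cap, bool)
        self.nchild = np.zeros(cap, np.int32)

    def _ensure(self, extra: int):
        cap = len(self.neuron)
        if self.n + extra <= cap:
            return
        new_cap = max(cap * 2, self.n + extra)
        for name in ("neuron", "kind", "parent", "prox", "dist", "diam", "alive", "nchild"):
            arr = getattr(self, name)
            shape = (new_cap,) + arr.shape[1:]
            new = np.empty(shape, arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def append_batch(self, neuron, kind, parent, prox, dist, diam) -> np.ndarray:
        m = len(neuron)
        self._ensure(m)
        sl = slice(self.n, self.n + m)
        self.neuron[sl] = neuron
        self.kind[sl] = kind
        self.parent[sl] = parent
        self.prox[sl] = prox
        self.dist[sl] = dist
        self.diam[sl] = diam
        self.alive[sl] = True
        self.nchild[sl] = 0
        par = np.asarray(parent)
        for p in par[par >= 0]:
            self.nchild[p] += 1
        ids = np.arange(self.n, self.n + m)
        self.n += m
        return ids


class GrowthState:
    """Vectorized lock-step growth of all cones of a population.

    All active growth cones advance synchronously; dt is chosen so one step
    covers half a discretization length (v_grow * dt = nu / 2).
    """

    def __init__(self, somata: Somata, params: dict | None = None,
                 seed: int | np.random.Generator = 0, gridded_field: bool = True):
        self.somata = somata
        self.params = dict(params or TABLE_GROWTH_PARAMS)
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

        Q = calibrate_secretion_rate()
        f_exc = SubstanceField(sources=somata.positions[~somata.is_excitatory], Q=Q)
        f_inh = SubstanceField(sources=somata.positions[somata.is_excitatory], Q=Q)
        self.field_for_exc_axons = f_exc
        self.field_for_inh_axons = f_inh
        if gridded_field:
            self._eval_exc = _GriddedField(f_exc, somata.cube_side)
            self._eval_inh = _GriddedField(f_inh, somata.cube_side)
        else:
            self._eval_exc = lambda p: np.atleast_1d(concentration_at(p, f_exc))
            self._eval_inh = lambda p: np.atleast_1d(concentration_at(p, f_inh))

        self.seg = _SegStore()
        self.synapse_segments: np.ndarray = np.zeros(0, bool)  # grown lazily
        self._sprout()
        self.dt = NU / 2.0 / 100.0  # v_grow * dt = nu / 2

    # -- setup ---------------------------------------------------------
    def _sprout(self):
        """One axonal and three dendritic cones per soma, random directions."""
        n = self.somata.n
        self.c_neuron = np.repeat(np.arange(n), 4)
        self.c_kind = np.tile(np.array([0, 1, 1, 1], np.int8), n)
        m = 4 * n
        self.c_dir = _random_unit(self.rng, m)
        radius = self.somata.diameter / 2.0
        self.c_pos = self.somata.positions[self.c_neuron] + radius * self.c_dir
        self.c_state = np.full(m, ELONGATING, np.int8)
        self.c_anchor = self.c_pos.copy()
        self.c_accum = np.zeros(m)
        self.c_last_seg = np.full(m, -1, np.int64)
        self.c_diam = np.empty(m)
        self.c_stop_reason = np.zeros(m, np.int8)
        self._assign_param_rows()
        for r, p in enumerate(self._rows):
            self.c_diam[self.c_row == r] = p.d_init

    def _assign_param_rows(self):
        """Map each cone to its (cell class, kind) parameter row."""
        keys = list(self.params)
        self._rows = [self.params[k] for k in keys]
        row_of = {}
        for r, (ct, kd) in enumerate(keys):
            row_of[(ct == "excitatory", _KIND[kd])] = r
        exc = self.somata.is_excitatory[self.c_neuron]
        self.c_row = np.array([row_of[(bool(e), int(k))]
                               for e, k in zip(exc, self.c_kind)], np.int8)
        self._pvec = {a: np.array([np.nan if getattr(p, a) is None else getattr(p, a)
                                   for p in self._rows])
                      for a in ("d_min", "dd_move", "dd_bif", "p_b0", "p_bc",
                                "v_grow", "v_retract", "e_low", "e_high",
                                "w_prev", "w_rand", "nu")}

    def _p(self, attr: str, idx=slice(None)) -> np.ndarray:
        return self._pvec[attr][self.c_row[idx]]

    # -- stepping ------------------------------------------------------
    def step(self):
        """Advance every active cone by one time step."""
        rng = self.rng
        is_axon = self.c_kind == 0

        # sensed concentration and retraction-state transitions (axons)
        C = np.zeros(len(self.c_neuron))
        ax = (self.c_state != STOPPED) & is_axon
        if ax.any():
            exc = self.somata.is_excitatory[self.c_neuron]
            for ev, mask in ((self._eval_exc, ax & exc), (self._eval_inh, ax & ~exc)):
                if mask.any():
                    C[mask] = ev(self.c_pos[mask])
            trig = ax & (self.c_state == ELONGATING) & (C < self._p("e_low"))
            self.c_state[trig] = RETRACTING
            resume = ax & (self.c_state == RETRACTING) & (C >= self._p("e_high"))
            if resume.any():
                self.c_state[resume] = ELONGATING
                self.c_dir[resume] = _random_unit(rng, int(resume.sum()))
                partial = np.flatnonzero(resume & (self.c_accum > 1e-9))
                if partial.size:
                    self._emit(partial)

        # ---- elongation ----
        idx = np.flatnonzero(self.c_state == ELONGATING)
        spawn = []
        if idx.size:
            u = _random_unit(rng, idx.size)
            d = (self._p("w_prev", idx)[:, None] * self.c_dir[idx]
                 + self._p("w_rand", idx)[:, None] * u)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            step_len = self._p("v_grow", idx) * self.dt
            self.c_dir[idx] = d
            self.c_pos[idx] += step_len[:, None] * d
            self.c_accum[idx] += step_len
            self.c_diam[idx] -= self._p("dd_move", idx)

            # batch segment emission at full discretization length
            emit = idx[self.c_accum[idx] >= self._p("nu", idx) - 1e-9]
            if emit.size:
                self._emit(emit)

            # bifurcation: emit any partial segment, then clone the cone
            p_b = np.clip(self._p("p_b0", idx) + self._p("p_bc", idx) * C[idx], 0, 1)
            branch = idx[rng.random(idx.size) < p_b]
            if branch.size:
                partial = branch[self.c_accum[branch] > 1e-9]
                if partial.size:
                    self._emit(partial)
                self.c_diam[branch] -= self._p("dd_bif", branch)
                spawn = branch[self.c_diam[branch] >= self._p("d_min", branch)]

            # stopping at minimal diameter
            stop = idx[self.c_diam[idx] < self._p("d_min", idx)]
            if stop.size:
                partial = stop[self.c_accum[stop] > 1e-9]
                if partial.size:
                    self._emit(partial)
                self.c_state[stop] = STOPPED
                self.c_stop_reason[stop] = STOP_TAPER

        # ---- retraction ----
        ret = np.flatnonzero(self.c_state == RETRACTING)
        if ret.size:
            self._retract(ret)

        # ---- batched cone spawning ----
        if len(spawn):
            self._spawn(np.asarray(spawn))

    def _emit(self, cones: np.ndarray):
        ids = self.seg.append_batch(
            self.c_neuron[cones], self.c_kind[cones], self.c_last_seg[cones],
            self.c_anchor[cones], self.c_pos[cones], self.c_diam[cones])
        self.c_last_seg[cones] = ids
        self.c_anchor[cones] = self.c_pos[cones]
        self.c_accum[cones] = 0.0

    def _spawn(self, cones: np.ndarray):
        """Clone cones at their tips with independent random perturbations."""
        u = _random_unit(self.rng, len(cones))
        d = (self._p("w_prev", cones)[:, None] * self.c_dir[cones]
             + self._p("w_rand", cones)[:, None] * u)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        self.c_neuron = np.concatenate([self.c_neuron, self.c_neuron[cones]])
        self.c_kind = np.concatenate([self.c_kind, self.c_kind[cones]])
        self.c_row = np.concatenate([self.c_row, self.c_row[cones]])
        self.c_dir = np.vstack([self.c_dir, d])
        self.c_pos = np.vstack([self.c_pos, self.c_pos[cones]])
        self.c_state = np.concatenate([self.c_state, np.full(len(cones), ELONGATING, np.int8)])
        self.c_anchor = np.vstack([self.c_anchor, self.c_pos[cones]])
        self.c_accum = np.concatenate([self.c_accum, np.zeros(len(cones))])
        self.c_last_seg = np.concatenate([self.c_last_seg, self.c_last_seg[cones]])
        self.c_diam = np.concatenate([self.c_diam, self.c_diam[cones]])
        self.c_stop_reason = np.concatenate([self.c_stop_reason,
                                             np.zeros(len(cones), np.int8)])

    def _retract(self, ret: np.ndarray):
        dist = self._p("v_retract", ret) * self.dt
        easy = self.c_accum[ret] > dist
        ei = ret[easy]
        if ei.size:
            vec = self.c_pos[ei] - self.c_anchor[ei]
            norm = np.linalg.norm(vec, axis=1, keepdims=True)
            norm[norm < 1e-12] = 1.0
            self.c_pos[ei] -= vec / norm * dist[easy, None]
            self.c_accum[ei] -= dist[easy]
        for ci, dd in zip(ret[~easy], dist[~easy]):
            self._retract_slow(ci, dd)

    def _retract_slow(self, ci: int, dist: float):
        """Retraction across segment boundaries (pops segments)."""
        while dist > 1e-12:
            if self.c_accum[ci] > 1e-9:
                d = min(self.c_accum[ci], dist)
                vec = self.c_pos[ci] - self.c_anchor[ci]
                norm = np.linalg.norm(vec)
                if norm > 1e-12:
                    self.c_pos[ci] -= vec / norm * d
                self.c_accum[ci] -= d
                dist -= d
            else:
                sid = self.c_last_seg[ci]
                if sid < 0:
                    self.c_state[ci] = STOPPED  # retracted back to the soma
                    self.c_stop_reason[ci] = STOP_SOMA
                    return
                if sid < len(self.synapse_segments) and self.synapse_segments[sid]:
                    self.c_state[ci] = STOPPED  # anchored by a synapse
                    self.c_stop_reason[ci] = STOP_ANCHOR
                    return
                if self.seg.nchild[sid] > 0 or np.sum(self.c_last_seg == sid) > 1:
                    # branch point (emitted children or sibling cones still
                    # rooted here) holds the arbor together
                    self.c_state[ci] = STOPPED
                    self.c_stop_reason[ci] = STOP_ANCHOR
                    return
                self.seg.alive[sid] = False
                self.c_anchor[ci] = self.seg.prox[sid]
                self.c_pos[ci] = self.seg.dist[sid].copy()
                self.c_accum[ci] = float(np.linalg.norm(self.seg.dist[sid] - self.seg.prox[sid]))
                par = self.seg.parent[sid]
                if par >= 0:
                    self.seg.nchild[par] -= 1
                self.c_last_seg[ci] = par

    def run(self, max_steps: int = 3000, callback=None, callback_every: int = 300):
        """Step until all cones stop (or ``max_steps``); optional epoch hook."""
        for t in range(max_steps):
            if not np.any(self.c_state != STOPPED):
                break
            self.step()
            if callback is not None and (t + 1) % callback_every == 0:
                callback(self, t + 1)
        return self

    # -- results -------------------------------------------------------
    def segments(self) -> dict:
        """Consolidated alive segments as arrays."""
        n = self.seg.n
        alive = self.seg.alive[:n]
        return {
            "neuron": self.seg.neuron[:n][alive],
            "kind": self.seg.kind[:n][alive],
            "prox": self.seg.prox[:n][alive],
            "dist": self.seg.dist[:n][alive],
            "diam": self.seg.diam[:n][alive],
            "seg_id": np.flatnonzero(alive),
        }

    def mark_synapse_segments(self, seg_ids: np.ndarray):
        if len(self.synapse_segments) < self.seg.n:
            grown = np.zeros(self.seg.n, bool)
            grown[: len(self.synapse_segments)] = self.synapse_segments
            self.synapse_segments = grown
        self.synapse_segments[np.asarray(seg_ids, int)] = True


def grow_network(somata: Somata, params: dict | None = None, seed=0,
                 max_steps: int = 3000, callback=None, callback_every: int = 300,
                 gridded_field: bool = True) -> GrowthState:
    """Grow all neurites of a placed population to completion."""
    gs = GrowthState(somata, params=params, seed=seed, gridded_field=gridded_field)
    gs.run(max_steps=max_steps, callback=callback, callback_every=callback_every)
    return gs


SYN_DTYPE = [("pre", int), ("post", int), ("pre_seg", int), ("post_seg", int),
             ("x", float), ("y", float), ("z", float),
             ("sign", int), ("weight", float)]


def form_synapses(gs: GrowthState, radius: float = SYNAPSE_RADIUS,
                  record: bool = True) -> np.ndarray:
    """All complementary bouton-spine pairs within ``radius``, no autapses.

    Boutons sit at axonal segment midpoints, spines at dendritic segment
    midpoints.  Returns a structured array sorted deterministically by
    (pre_seg, post_seg); excitatory synapses start at weight 0.001,
    inhibitory at 0.01 (sign from the presynaptic cell class).
    """
    seg = gs.segments()
    mid = (seg["prox"] + seg["dist"]) / 2.0
    is_ax = seg["kind"] == _KIND["axon"]
    b_idx = np.flatnonzero(is_ax)
    s_idx = np.flatnonzero(~is_ax)
    rows = []
    if b_idx.size and s_idx.size:
        tb = cKDTree(mid[b_idx])
        ts = cKDTree(mid[s_idx])
        pairs = tb.query_ball_tree(ts, radius)
        for bi, lst in enumerate(pairs):
            if not lst:
                continue
            gb = b_idx[bi]
            pre = seg["neuron"][gb]
            for si in lst:
                gd = s_idx[si]
                post = seg["neuron"][gd]
                if pre == post:
                    continue
                rows.append((pre, post, gb, gd))
    res = np.zeros(len(rows), dtype=SYN_DTYPE)
    if rows:
        raw = np.array(rows)
        order = np.lexsort((raw[:, 3], raw[:, 2]))
        raw = raw[order]
        res["pre"] = seg["neuron"][raw[:, 2]]
        res["post"] = seg["neuron"][raw[:, 3]]
        res["pre_seg"] = seg["seg_id"][raw[:, 2]]
        res["post_seg"] = seg["seg_id"][raw[:, 3]]
        pos = (mid[raw[:, 2]] + mid[raw[:, 3]]) / 2.0
        res["x"], res["y"], res["z"] = pos[:, 0], pos[:, 1], pos[:, 2]
        pre_exc = gs.somata.is_excitatory[res["pre"]]
        res["sign"] = np.where(pre_exc, 1, -1)
        res["weight"] = np.where(pre_exc, W_INIT_EXC, W_INIT_INH)
        if record:
            gs.mark_synapse_segments(np.concatenate([res["pre_seg"], res["post_seg"]]))
    return res


def brute_force_synapses(gs: GrowthState, radius: float = SYNAPSE_RADIUS) -> set:
    """O(n^2) all-pairs proximity scan; independent oracle for form_synapses."""
    seg = gs.segments()
    mid = (seg["prox"] + seg["dist"]) / 2.0
    res = set()
    n = len(seg["neuron"])
    for i in range(n):
        if seg["kind"][i] != _KIND["axon"]:
            continue
        for j in range(n):
            if seg["kind"][j] != _KIND["dendrite"]:
                continue
            if seg["neuron"][i] == seg["neuron"][j]:
                continue
            if np.linalg.norm(mid[i] - mid[j]) <= radius:
                res.add((int(seg["seg_id"][i]), int(seg["seg_id"][j])))
    return res


def connectivity_stats(synapses: np.ndarray, is_excitatory: np.ndarray) -> dict:
    """Connectivity summary of a synapse list.

    Returns per-(pre,post) class synapse totals, the same normalized to the
    E->E entry, per-class mean counts per postsynaptic neuron, the per-neuron
    percentage of excitatory input synapses with its mean, and the neurons
    lacking any input or lacking inhibitory input.
    """
    if len(synapses) == 0:
        raise ValueError("need at least one synapse")
    pre_e = is_excitatory[synapses["pre"]]
    post_e = is_excitatory[synapses["post"]]
    n_exc = int(is_excitatory.sum())
    n_inh = int((~is_excitatory).sum())
    totals = {}
    means = {}
    for (pe, po), label in (((1, 1), "EE"), ((0, 1), "IE"), ((1, 0), "EI"), ((0, 0), "II")):
        cnt = int(np.sum((pre_e == bool(pe)) & (post_e == bool(po))))
        totals[label] = cnt
        means[label] = cnt / (n_exc if po else max(n_inh, 1))
    ref = max(totals["EE"], 1)
    proportions = {k: v / ref for k, v in totals.items()}

    n = len(is_excitatory)
    exc_in = np.bincount(synapses["post"][pre_e], minlength=n)
    inh_in = np.bincount(synapses["post"][~pre_e], minlength=n)
    tot_in = exc_in + inh_in
    has_input = tot_in > 0
    pct = 100.0 * exc_in[has_input] / tot_in[has_input]
    return {
        "totals": totals,
        "proportions": proportions,
        "mean_counts_per_post": means,
        "pct_excitatory_inputs": pct,
        "mean_pct_excitatory_inputs": float(pct.mean()),
        "neurons_without_input": np.flatnonzero(~has_input),
        "neurons_without_inhibitory_input": np.flatnonzero(has_input & (inh_in == 0)),
    }


def export_swc(gs: GrowthState, neuron_id: int) -> str:
    """SWC text for one neuron (type 2 = axon, 3 = dendrite)."""
    seg = gs.segments()
    mask = seg["neuron"] == neuron_id
    lines = []
    soma = gs.somata.positions[neuron_id]
    lines.append(f"1 1 {soma[0]:.3f} {soma[1]:.3f} {soma[2]:.3f} "
                 f"{gs.somata.diameter / 2:.3f} -1")
    remap = {-1: 1}
    nid = 2
    order = np.flatnonzero(mask)
    for k in order:
        remap[int(seg["seg_id"][k])] = nid
        nid += 1
    nid = 2
    for k in order:
        sid = int(seg["seg_id"][k])
        parent = int(gs.seg.parent[sid])
        p = remap.get(parent, 1)
        t = 2 if seg["kind"][k] == _KIND["axon"] else 3
        x, y, z = seg["dist"][k]
        lines.append(f"{nid} {t} {x:.3f} {y:.3f} {z:.3f} {seg['diam'][k] / 2:.3f} {p}")
        nid += 1
    return "\n".join(lines) + "\n"
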