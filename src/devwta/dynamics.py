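"""Rate-based electrophysiology on the summed connection-weight matrix.

Neurons are linear-threshold units:

    tau * dr_i/dt = -r_i + max(0, s_i + x_i + sum_j w_ij r_j - T)

integrated with explicit Euler and clipped to [0, r_max].  The recurrent
weights are the per-connection sums of individual synapse weights; each
connection carries a cap equal to its synapse count times the maximal weight
of a single synapse (0.1), so neurons joined by few synapses cannot form a
strong functional link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkWeights", "RateState", "rate_step", "steady_state", "apply_caps",
           "W_MAX_SINGLE", "R_MAX"]

W_MAX_SINGLE = 0.1  # maximal weight of a single synapse
R_MAX = 250.0       # maximal firing rate (Hz)


@dataclass
class NetworkWeights:
    """Signed summed connection weights with synapse-count-derived caps.

    ``w[i, j]`` is the summed weight of the connection from presynaptic
    neuron j onto postsynaptic neuron i (negative for inhibitory j);
    ``n_syn[i, j]`` the number of synapses forming that connection.
    """

    w: np.ndarray
    n_syn: np.ndarray
    w_max_single: float = W_MAX_SINGLE

    @property
    def cap(self) -> np.ndarray:
        return self.n_syn * self.w_max_single

    def validate_signs(self, is_excitatory: np.ndarray) -> bool:
        """Weights from excitatory columns must be >= 0, inhibitory <= 0."""
        exc_ok = np.all(self.w[:, is_excitatory] >= 0)
        inh_ok = np.all(self.w[:, ~is_excitatory] <= 0)
        return bool(exc_ok and inh_ok)


@dataclass
class RateState:
    r: np.ndarray
    x: np.ndarray
    s: np.ndarray
    T: float = 0.0
    tau: float = 1.0
    r_max: float = R_MAX


def rate_step(state: RateState, W: NetworkWeights | np.ndarray, dt: float) -> RateState:
    """One explicit-Euler step of the linear-threshold rate equation."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = W.w if isinstance(W, NetworkWeights) else W
    drive = np.maximum(0.0, state.s + state.x + w @ state.r - state.T)
    r_new = state.r + (dt / state.tau) * (-state.r + drive)
    if not np.all(np.isfinite(r_new)):
        bad = int(np.flatnonzero(~np.isfinite(r_new))[0])
        raise FloatingPointError(f"non-finite firing rate at neuron {bad}")
    r_new = np.clip(r_new, 0.0, state.r_max)
    return RateState(r=r_new, x=state.x, s=state.s, T=state.T, tau=state.tau,
                     r_max=state.r_max)


def steady_state(W: NetworkWeights | np.ndarray, x: np.ndarray, s: np.ndarray | float = 0.0,
                 n_iter: int = 3000, dt: float = 0.01, tau: float = 1.0,
                 T: float = 0.0, r0: np.ndarray | None = None,
                 conv_tol: float = 1e-6):
    """Relax the network to steady state by repeated Euler stepping.

    Returns ``(state, converged)``; convergence means the max rate change
    over the last 10 iterations stayed below ``conv_tol``.  A warning is
    raised if the excitatory population saturates at the rate ceiling
    (runaway excitation).
    """
    w = W.w if isinstance(W, NetworkWeights) else W
    n = w.shape[0]
    x = np.broadcast_to(np.asarray(x, float), (n,))
    s = np.broadcast_to(np.asarray(s, float), (n,))
    state = RateState(r=np.zeros(n) if r0 is None else np.array(r0, float),
                      x=x, s=s, T=T, tau=tau)
    max_delta = np.inf
    for it in range(n_iter):
        prev = state.r
        state = rate_step(state, w, dt)
        if it >= n_iter - 10:
            d = float(np.max(np.abs(state.r - prev)))
            max_delta = d if max_delta is np.inf else max(max_delta, d)
    converged = bool(max_delta < conv_tol)
    if np.all(state.r >= state.r_max - 1e-9) and n > 0:
        import warnings

        warnings.warn("runaway excitation: rates pinned at the ceiling")
    return state, converged


def solve_fixed_point(w: np.ndarray, x: np.ndarray, s: np.ndarray | float = 0.0,
                      T: float = 0.0, max_iter: int = 200) -> np.ndarray:
    """Direct solve of the piecewise-linear fixed point r = max(0, s+x+Wr-T).

    Iterates over active sets: given a guess of which neurons are above
    threshold, solves the linear system restricted to the active set and
    checks consistency.  Intended as an independent cross-check on small
    (<= ~30 neuron) instances with sub-critical recurrent gain.
    """
    n = w.shape[0]
    x = np.broadcast_to(np.asarray(x, float), (n,)).copy()
    s = np.broadcast_to(np.asarray(s, float), (n,)).copy()
    b = s + x - T
    active = b > 0
    for _ in range(max_iter):
        r = np.zeros(n)
        idx = np.flatnonzero(active)
        if idx.size:
            A = np.eye(idx.size) - w[np.ix_(idx, idx)]
            r[idx] = np.linalg.solve(A, b[idx])
        drive = b + w @ r
        new_active = drive > 0
        if np.array_equal(new_active, active) and np.all(r[idx] >= -1e-12):
            return np.maximum(r, 0.0)
        active = new_active
    raise RuntimeError("active-set iteration did not converge")


def apply_caps(W: NetworkWeights) -> NetworkWeights:
    """Clip each connection's magnitude to its synapse-count-derived cap."""
    np.clip(W.w, -W.cap, W.cap, out=W.w)
    return W
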