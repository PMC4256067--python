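"""Functional characterization of grown and learned networks.

Measures soft winner-take-all behavior (per-neuron gain under a preferred
stimulus), response decorrelation (cosine similarity of population response
vectors), orientation selectivity (OSI from ring-position tuning curves),
the structure of inhibition (recursively effective exertion, REE = activity
times connection weight), stimulus competition curves, and a 1-D topological
reordering of the excitatory weight matrix for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningCurve",
    "gain_profile",
    "response_similarity",
    "osi",
    "ree",
    "ree_breakdown",
    "competition_curve",
    "order_neurons",
    "ordering_energy",
]


@dataclass
class TuningCurve:
    """Mean steady-state response of one neuron per stimulus angle.

    Angles come from ring position: position k of n maps to 180*k/n degrees.
    """

    neuron_id: int
    angles: np.ndarray
    responses: np.ndarray


def gain_profile(rates: np.ndarray, x: np.ndarray, converged: bool = True):
    """Per-neuron gain r_i / x_i (steady rate over feed-forward drive).

    Neurons with zero feed-forward drive have undefined gain (NaN).
    Refuses non-converged steady states.
    """
    if not converged:
        raise RuntimeError("steady state did not converge; gain undefined")
    rates = np.asarray(rates, float)
    x = np.asarray(x, float)
    gain = np.full_like(rates, np.nan)
    nz = x > 0
    gain[nz] = rates[nz] / x[nz]
    return gain


def response_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized scalar product of two population response vectors.

    Close to 0 for very different responses, close to 1 for correlated ones.
    Undefined (NaN) if both vectors are zero.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("response vectors must have the same dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 and nb == 0:
        return float("nan")
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def osi(curve: TuningCurve | np.ndarray) -> float:
    """Orientation selectivity index in [0, 1].

    OSI = (R_pref - R_orth) / (R_pref + R_orth) with the preferred angle at
    the curve's maximum and the orthogonal response 90 degrees away (half the
    ring).  0 for a flat curve, 1 for a single-angle response; NaN if the
    curve is identically zero.
    """
    resp = curve.responses if isinstance(curve, TuningCurve) else np.asarray(curve, float)
    if np.any(resp < 0):
        raise ValueError("responses must be non-negative")
    if np.all(resp == 0):
        return float("nan")
    n = len(resp)
    k_pref = int(np.argmax(resp))
    k_orth = (k_pref + n // 2) % n
    r_p, r_o = resp[k_pref], resp[k_orth]
    return float((r_p - r_o) / (r_p + r_o))


def ree(r_pre: np.ndarray | float, w: np.ndarray | float):
    """Recursively effective exertion: presynaptic activity times weight."""
    return np.asarray(r_pre, float) * np.asarray(w, float)


def ree_breakdown(rates: np.ndarray, w_row: np.ndarray,
                  inhibitory_idx: np.ndarray) -> np.ndarray:
    """Percentage of total inhibitory REE per inhibitory afferent of a neuron.

    ``w_row`` is the input-weight row of the postsynaptic neuron, ``rates``
    the steady-state activities under the stimulus.  Returns percentages over
    ``inhibitory_idx`` summing to 100 (empty if no inhibitory input).
    """
    contrib = np.abs(ree(rates[inhibitory_idx], w_row[inhibitory_idx]))
    total = contrib.sum()
    if total == 0:
        return np.zeros(0)
    return 100.0 * contrib / total


def competition_curve(respond, pattern_a: np.ndarray, pattern_b: np.ndarray,
                      pop_a: np.ndarray, pop_b: np.ndarray,
                      lambda_grid: np.ndarray):
    """Normalized subpopulation activities across stimulus mixtures.

    ``respond(x)`` maps an input pattern to steady-state network rates;
    ``pop_a``/``pop_b`` index the neurons preferring each pattern.  For each
    mixture proportion lam the mean activities of the two subpopulations are
    normalized to sum to 1.  Returns (share_a, share_b) arrays.
    """
    if len(pop_a) == 0 or len(pop_b) == 0:
        raise ValueError("undefined subpopulation: no neuron prefers a pattern")
    from .stimuli import mixture_input

    share_a, share_b = [], []
    for lam in lambda_grid:
        r = respond(mixture_input(pattern_a, pattern_b, float(lam)))
        ma, mb = float(np.mean(r[pop_a])), float(np.mean(r[pop_b]))
        tot = ma + mb
        if tot == 0:
            share_a.append(0.5)
            share_b.append(0.5)
        else:
            share_a.append(ma / tot)
            share_b.append(mb / tot)
    return np.array(share_a), np.array(share_b)


def network_gain(state, is_excitatory: np.ndarray, n_pops: int = 20,
                 n_iter: int = 4000, dt: float = 0.05,
                 summary: str = "median") -> float:
    """Recurrent gain of a learned winner-take-all network.

    Presents the noise-free hill at every ring position, finds the winning
    excitatory neuron (the highest steady-state rate), and reports the
    median over positions of the winner's rate divided by its feed-forward
    drive.  The winner is by construction a well-driven neuron, which keeps
    the ratio meaningful (per-neuron gain diverges for neurons with
    negligible drive).
    """
    from .learning import respond
    from .stimuli import wave_input

    rng0 = np.random.default_rng(0)
    gains = []
    for k in range(n_pops):
        x = wave_input(k, n_pops, rng0)
        x[x <= 0.07] = 0.0  # strip baseline noise: deterministic probe
        r, xin, _ = respond(state, x, s=0.0, n_iter=n_iter, dt=dt)
        win = int(np.argmax(np.where(is_excitatory, r, -np.inf)))
        if xin[win] > 0:
            gains.append(r[win] / xin[win])
    agg = np.median if summary == "median" else np.mean
    return float(agg(gains))


def ordering_energy(w: np.ndarray, perm: np.ndarray) -> float:
    """Sum of weighted 1-D topological distances under a permutation.

    ``perm[k]`` is the neuron placed at position k; the energy is
    sum_ij w_ij * |pos_i - pos_j|.
    """
    pos = np.empty(len(perm), int)
    pos[perm] = np.arange(len(perm))
    d = np.abs(pos[:, None] - pos[None, :])
    return float(np.sum(w * d))


def order_neurons(w: np.ndarray, rng: np.random.Generator | None = None,
                  n_iter: int = 20000, t0: float = None) -> np.ndarray:
    """1-D ordering of neurons minimizing the weighted-distance energy.

    Simulated annealing over permutations with pair-swap moves; any
    optimizer is acceptable as long as the final energy beats random
    orderings, and annealing is simple and dependency-free.
    Returns the permutation (neuron ids in display order).
    """
    n = w.shape[0]
    if rng is None:
        rng = np.random.default_rng(0)
    ws = (w + w.T) / 2.0  # energy is symmetric in |pos_i - pos_j|
    perm = rng.permutation(n)
    energy = ordering_energy(ws, perm)
    if t0 is None:
        t0 = max(energy / max(n, 1), 1e-12)
    for it in range(n_iter):
        t = t0 * (1.0 - it / n_iter) + 1e-12
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        cand = perm.copy()
        cand[i], cand[j] = cand[j], cand[i]
        e2 = ordering_energy(ws, cand)
        if e2 < energy or rng.random() < np.exp((energy - e2) / t):
            perm, energy = cand, e2
    return perm
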