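"""Homeostatic synaptic scaling and BCM learning.

Weight calibration runs in two sequential developmental phases:

* **Homeostatic phase** — every synapse follows multiplicative synaptic
  scaling toward a class-specific target mean rate ``a_goal``:

      dw = (dt / tau_scal) * (a_goal_i - abar_i) * w

  All of a neuron's input weights share one multiplicative factor, so each
  neuron's excitation/inhibition ratio is preserved while its total drive
  moves toward the target.

* **Specification phase** — synapses onto excitatory neurons (excitatory and
  inhibitory alike) switch to the BCM rule with a sliding threshold:

      dw = (dt / tau_bcm) * r_pre * r_post * (r_post - theta_i) * w
      theta_i = c_i * <r_i^2>,   c_i = 1 / a_goal_i

  while synapses onto inhibitory neurons keep scaling.  Both rules are linear
  in the synaptic weight, so evolving the summed connection-weight matrix is
  exactly equivalent to evolving individual synapse weights and summing.

Every learning step is clamped to at most 3% of the current weight magnitude,
and connection magnitudes never exceed their synapse-count-derived caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HomeostasisParams",
    "ActivityAverage",
    "scaling_update",
    "bcm_update",
    "theta_update",
    "clamp_step",
    "rule_router",
]

MAX_REL_CHANGE = 0.03


@dataclass
class HomeostasisParams:
    """Targets and time constants of the two-phase weight calibration.

    ``a_goal_E`` is the target mean rate of excitatory neurons (0.14-0.68 Hz);
    inhibitory neurons aim higher (default 2x).  ``c_i = 1/a_goal`` of a
    neuron's class makes the BCM stationary rate equal the homeostatic
    target.  Time constants are expressed per learning step (one step per
    stimulus period in every input mode).
    """

    a_goal_E: float = 0.4
    a_goal_I_factor: float = 2.0
    tau_scal: float = 1.0
    tau_bcm: float = 1.0
    max_rel_change: float = MAX_REL_CHANGE

    def __post_init__(self):
        if not 0 < self.a_goal_E:
            raise ValueError("a_goal_E must be positive")
        if self.a_goal_I_factor <= 1:
            raise ValueError("inhibitory target must exceed excitatory")
        if self.tau_scal <= 0 or self.tau_bcm <= 0:
            raise ValueError("time constants must be positive")

    @property
    def a_goal_I(self) -> float:
        return self.a_goal_I_factor * self.a_goal_E

    def a_goal(self, is_excitatory: np.ndarray) -> np.ndarray:
        return np.where(is_excitatory, self.a_goal_E, self.a_goal_I)

    def c(self, is_excitatory: np.ndarray) -> np.ndarray:
        return 1.0 / self.a_goal(is_excitatory)


class ActivityAverage:
    """Ring buffer of the last N sampled rates per neuron.

    N is twice the number of input populations (waves) or twice the number of
    discrete patterns, i.e. one full active/non-active presentation period,
    so the average spans every possible input.  Exposes the arithmetic mean
    ``a_bar`` and the mean of squared rates ``a_sq_bar``.
    """

    def __init__(self, n_neurons: int, window: int):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self._buf = np.zeros((window, n_neurons))
        self._count = 0
        self._pos = 0

    def push(self, rates: np.ndarray):
        self._buf[self._pos] = rates
        self._pos = (self._pos + 1) % self.window
        self._count = min(self._count + 1, self.window)

    @property
    def warmed_up(self) -> bool:
        return self._count >= self.window

    @property
    def a_bar(self) -> np.ndarray:
        if self._count == 0:
            raise RuntimeError("no samples yet")
        return self._buf[: self._count].mean(axis=0)

    @property
    def a_sq_bar(self) -> np.ndarray:
        if self._count == 0:
            raise RuntimeError("no samples yet")
        return (self._buf[: self._count] ** 2).mean(axis=0)


def clamp_step(w_old: np.ndarray, w_new: np.ndarray,
               max_rel: float = MAX_REL_CHANGE) -> np.ndarray:
    """Limit the per-step weight change to ``max_rel`` of the current value."""
    w_old = np.asarray(w_old, float)
    w_new = np.asarray(w_new, float)
    lim = max_rel * np.abs(w_old)
    return w_old + np.clip(w_new - w_old, -lim, lim)


def scaling_update(w: np.ndarray, a_bar: np.ndarray, a_goal: np.ndarray,
                   tau_scal: float, dt: float) -> np.ndarray:
    """Multiplicative synaptic scaling toward the target mean rate.

    dw = (dt/tau) * (a_goal_i - abar_i) * w

    ``w`` has shape (post, pre); ``a_bar``/``a_goal`` are per-postsynaptic-
    neuron.  All of a neuron's input weights are multiplied by a common
    factor: below target both excitatory drive and inhibitory drive grow in
    magnitude, above target both shrink (the net rate moves toward the
    target because excitation dominates the input mix).  Crucially this
    preserves each neuron's excitation/inhibition ratio, so the balance laid
    down by synaptogenesis survives homeostasis.  A weight of zero stays
    zero; the per-step clamp is applied here, the cap is the caller's
    concern.
    """
    delta = (dt / tau_scal) * (np.asarray(a_goal) - np.asarray(a_bar))[:, None] * w
    return clamp_step(w, w + delta)


def theta_update(avg: ActivityAverage, c: np.ndarray) -> np.ndarray:
    """Sliding BCM threshold theta_i = c_i * <r_i^2> over the window."""
    return np.asarray(c) * avg.a_sq_bar


def bcm_update(w: np.ndarray, r_pre: np.ndarray, r_post: np.ndarray,
               theta: np.ndarray, tau_bcm: float, dt: float) -> np.ndarray:
    """BCM step on the (post, pre) weight block.

    ``r_pre``/``r_post`` may be vectors (one sample) or (n_samples, n)
    arrays, in which case the Hebbian term is averaged over samples.
    """
    r_pre = np.atleast_2d(np.asarray(r_pre, float))
    r_post = np.atleast_2d(np.asarray(r_post, float))
    theta = np.asarray(theta, float)
    # mean over samples of r_post*(r_post-theta) x r_pre
    hebb = np.einsum("ti,tj->ij", r_post * (r_post - theta[None, :]), r_pre) / r_pre.shape[0]
    delta = (dt / tau_bcm) * hebb * w
    return clamp_step(w, w + delta)


def rule_router(post_is_excitatory: np.ndarray, phase: str,
                variant: str = "default") -> np.ndarray:
    """Which rule each postsynaptic neuron's input synapses follow.

    Returns a boolean vector, True where the BCM rule applies.  During the
    homeostatic phase everything scales.  During specification, synapses onto
    excitatory neurons follow BCM (the default routing); the ``all-bcm``
    control variant applies BCM onto inhibitory neurons as well.
    """
    post_is_excitatory = np.asarray(post_is_excitatory, bool)
    if phase not in ("homeostatic", "specification"):
        raise ValueError(f"unknown phase {phase!r}")
    if variant not in ("default", "all-bcm"):
        raise ValueError(f"unknown variant {variant!r}")
    if phase == "homeostatic":
        return np.zeros_like(post_is_excitatory)
    if variant == "all-bcm":
        return np.ones_like(post_is_excitatory)
    return post_is_excitatory.copy()
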