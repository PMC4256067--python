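"""Feed-forward input regimes.

Two stimulation scenarios drive learning: (i) a hill of activity moving
periodically over a 1-D ring of input populations (a stylized retinal wave,
or equivalently a rotating oriented bar when ring position is read as an
angle in [0, 180) degrees), and (ii) discrete bar patterns on a 3x3 grid.
Input populations alternate between active and non-active presentations; in
the non-active mode the network is driven only by its spontaneous activity.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "HILL_PROFILE",
    "WAVE_PEAK_RATE",
    "PATTERN_ACTIVE_RATE",
    "BASELINE_INTERVAL",
    "wave_input",
    "bar_patterns",
    "noisy_stimulus",
    "mixture_input",
    "init_input_weights",
    "StimulusSchedule",
]

# hill of activity: rate of the center population and fractions applied at
# ring distances 0..3; populations farther than 3 get baseline noise
WAVE_PEAK_RATE = 1.4
HILL_PROFILE = np.array([1.0, 0.5, 0.25, 0.125])
PATTERN_ACTIVE_RATE = 2.1
BASELINE_INTERVAL = (0.0, 0.06)


def wave_input(center_k: int, n_pops: int, rng: np.random.Generator,
               peak: float = WAVE_PEAK_RATE, profile: np.ndarray = HILL_PROFILE,
               baseline: tuple = BASELINE_INTERVAL) -> np.ndarray:
    """Hill-shaped rate vector centered on input population ``center_k``.

    The center fires at ``peak`` Hz and the rate decays with ring distance
    according to ``profile``; populations beyond the hill fire at a random
    baseline rate drawn uniformly from ``baseline``.
    """
    if not 0 <= center_k < n_pops:
        raise ValueError("center_k out of range")
    if n_pops < 2 * (len(profile) - 1) + 1:
        import warnings

        warnings.warn("hill truncated: fewer populations than hill width")
    x = rng.uniform(*baseline, size=n_pops)
    idx = np.arange(n_pops)
    dist = np.minimum((idx - center_k) % n_pops, (center_k - idx) % n_pops)
    inside = dist < len(profile)
    x[inside] = peak * profile[dist[inside]]
    return x


def bar_patterns(grid: int = 3, subset4: bool = False) -> np.ndarray:
    """Binary bar patterns on a square grid, flattened row-major.

    The full set holds ``grid`` rows + ``grid`` columns + 2 diagonals
    (8 patterns for the default 3x3 grid).  ``subset4`` selects the
    4-pattern subset: middle row (horizontal), middle column (vertical) and
    both diagonals.
    """
    g = grid
    pats = []
    for r in range(g):
        m = np.zeros((g, g))
        m[r, :] = 1
        pats.append(m)
    for c in range(g):
        m = np.zeros((g, g))
        m[:, c] = 1
        pats.append(m)
    d1 = np.eye(g)
    d2 = np.fliplr(np.eye(g))
    pats += [d1, d2]
    pats = np.array([p.ravel() for p in pats])
    if subset4:
        mid = g // 2
        keep = [mid, g + mid, 2 * g, 2 * g + 1]
        pats = pats[keep]
    return pats


def noisy_stimulus(pattern: np.ndarray, M: float = 10.0, eta: float = 0.0,
                   rng: np.random.Generator | None = None,
                   noise_interval: tuple | None = None) -> np.ndarray:
    """Rate vector for a binary pattern with amplitude M and uniform noise.

    x_k = M * pattern_k + xi_k with xi uniform on ``noise_interval``
    (default symmetric interval of half-width eta*M/2).  Negative rates are
    floored at zero.
    """
    if M <= 0:
        raise ValueError("amplitude M must be positive")
    if eta < 0:
        raise ValueError("noise level eta must be >= 0")
    x = M * np.asarray(pattern, dtype=float)
    if eta > 0:
        if rng is None:
            raise ValueError("rng required when eta > 0")
        if noise_interval is None:
            half = eta * M / 2.0
            noise_interval = (-half, half)
        x = x + rng.uniform(*noise_interval, size=x.shape)
    return np.maximum(x, 0.0)


def mixture_input(pattern_a: np.ndarray, pattern_b: np.ndarray, lam: float) -> np.ndarray:
    """Convex mixture (1-lam)*a + lam*b of two patterns (before noise)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("mixture proportion must lie in [0, 1]")
    return (1.0 - lam) * np.asarray(pattern_a, float) + lam * np.asarray(pattern_b, float)


def init_input_weights(n_pops: int, n_neurons: int, rng: np.random.Generator,
                       interval: tuple = (0.001, 0.01)) -> np.ndarray:
    """Fully connected input weights, i.i.d. uniform on ``interval``.

    Returns an (n_neurons, n_pops) non-negative matrix.
    """
    if n_pops <= 0 or n_neurons <= 0:
        raise ValueError("counts must be positive")
    return rng.uniform(interval[0], interval[1], size=(n_neurons, n_pops))


class StimulusSchedule:
    """Iterator over (input-rate vector, active-flag) presentations.

    ``wave`` mode sweeps the hill center over all ring positions; ``patterns``
    mode cycles through the discrete pattern set.  When ``alternate`` is on,
    every active presentation is followed by a non-active one (all-zero input)
    so instructive input is intermittent in time.
    """

    def __init__(self, mode: str, n_pops: int, rng: np.random.Generator,
                 patterns: np.ndarray | None = None, alternate: bool = True,
                 peak: float = WAVE_PEAK_RATE, eta: float = 0.0, M: float = PATTERN_ACTIVE_RATE):
        if mode not in ("wave", "patterns", "silent"):
            raise ValueError(f"unknown stimulus mode {mode!r}")
        self.mode = mode
        self.n_pops = n_pops
        self.rng = rng
        self.alternate = alternate
        self.patterns = patterns
        self.peak = peak
        self.eta = eta
        self.M = M

    def period(self):
        """One full period of presentations (a sweep over all stimuli)."""
        if self.mode == "silent":
            yield np.zeros(self.n_pops), False
            return
        if self.mode == "wave":
            items = range(self.n_pops)
        else:
            items = range(len(self.patterns))
        for k in items:
            if self.mode == "wave":
                x = wave_input(k, self.n_pops, self.rng, peak=self.peak)
            else:
                base = self.patterns[k]
                x = self.M * base + self.rng.uniform(*BASELINE_INTERVAL, size=base.shape) * (base == 0)
            yield x, True
            if self.alternate:
                yield np.zeros(self.n_pops), False

    def n_per_period(self) -> int:
        if self.mode == "silent":
            return 1
        n = self.n_pops if self.mode == "wave" else len(self.patterns)
        return n * (2 if self.alternate else 1)
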