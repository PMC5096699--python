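"""Inhomogeneous-Poisson population spike-train simulator.

Ground truth is a set of "block" firing-rate patterns: rectangular regions
of elevated (foreground) rate on a low background rate, laid out over T
time bins and N neurons.  On each trial a subset of patterns is active
(either independently with a presence probability, or fixed per stimulus
condition), the active rate maps are superimposed, and spike counts are
drawn per bin as Poisson(rate * bin_width).

Pattern SNR is the ratio of foreground to background firing rate; pattern
overlap is the mean pairwise geodesic similarity of the foreground rate
patterns (background subtracted), in percent.

Canonical geometry (all overridable): N = 20 neurons, T = 30 bins of
10 ms, four blocks of 6 neurons x 8 bins arranged as two neuron groups
by two time intervals.  The ``overlap`` preset shifts the groups and
intervals so that adjacent blocks share (o_n neurons, o_t bins) per level,
spanning mean pattern overlaps from about 9.8% (level 0) to about 32.2%
(level 3) while keeping the block area constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core_data import TrialTensor
from .similarity import geodesic_similarity

# (neurons shared, bins shared) between adjacent blocks per overlap level;
# calibrated so mean pairwise overlap spans ~9.8% to ~32.2% monotonically.
OVERLAP_LEVELS = {0: (1, 2), 1: (2, 2), 2: (1, 4), 3: (3, 5)}


@dataclass
class RatePatternSet:
    """Ground-truth firing-rate patterns.

    Attributes
    ----------
    patterns : list of ndarray, each (T, N)
        Rate maps in Hz, background everywhere except the foreground cells.
    background_rate : float
        Background rate in Hz (> 0).
    bin_width : float
        Bin width in ms used when drawing spike counts.
    """

    patterns: list = field(default_factory=list)
    background_rate: float = 2.0
    bin_width: float = 10.0

    def __post_init__(self) -> None:
        self.patterns = [np.asarray(p, dtype=float) for p in self.patterns]
        if self.patterns:
            shape = self.patterns[0].shape
            for p in self.patterns:
                if p.shape != shape:
                    raise ValueError("all patterns must share (T, N) shape")
                if np.any(p < 0):
                    raise ValueError("rates must be non-negative")
                if np.any((p > 0) & (p < self.background_rate - 1e-12)):
                    raise ValueError(
                        "foreground cells must be at or above background rate"
                    )

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    @property
    def n_bins(self) -> int:
        return self.patterns[0].shape[0]

    @property
    def n_neurons(self) -> int:
        return self.patterns[0].shape[1]

    def foreground_excess(self) -> list:
        """Patterns with the background subtracted (>= 0 everywhere)."""
        return [np.maximum(p - self.background_rate, 0.0) for p in self.patterns]


@dataclass
class PresenceDesign:
    """Which patterns are active on each trial.

    ``independent_mixture``: each pattern is present independently with
    ``presence_probability``; the trial label records the active subset.
    ``fixed_conditions``: ``condition_table`` maps each stimulus label to
    the (non-empty) tuple of active pattern indices.
    """

    mode: str
    presence_probability: float = 0.5
    condition_table: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("independent_mixture", "fixed_conditions"):
            raise ValueError(f"unknown presence mode {self.mode!r}")
        if self.mode == "independent_mixture":
            if not 0.0 <= self.presence_probability <= 1.0:
                raise ValueError("presence probability must be in [0, 1]")
        else:
            if not self.condition_table:
                raise ValueError("fixed_conditions requires a condition table")
            for label, subset in self.condition_table.items():
                if len(subset) == 0:
                    raise ValueError(f"empty pattern subset for stimulus {label!r}")

    @classmethod
    def mixture(cls, presence_probability: float = 0.5) -> "PresenceDesign":
        return cls("independent_mixture", presence_probability=presence_probability)

    @classmethod
    def conditions(cls, table: dict) -> "PresenceDesign":
        return cls("fixed_conditions", condition_table=dict(table))


def pair_conditions(n_patterns: int = 4) -> dict:
    """The stimulus set with exactly two blocks per condition.

    All unordered pairs of the ``n_patterns`` blocks; 4 blocks give the
    canonical 6 stimulus conditions.
    """
    return {
        f"{i}+{j}": (i, j) for i, j in combinations(range(n_patterns), 2)
    }


def _block(n_bins, n_neurons, bins, neurons, fg, bg):
    pattern = np.full((n_bins, n_neurons), bg, dtype=float)
    t0, t1 = bins
    n0, n1 = neurons
    if not (0 <= t0 < t1 <= n_bins and 0 <= n0 < n1 <= n_neurons):
        raise ValueError(
            f"block bins {bins} x neurons {neurons} exceeds "
            f"({n_bins}, {n_neurons}) bounds"
        )
    pattern[t0:t1, n0:n1] = fg
    return pattern


def _grid_blocks(n_bins, n_neurons, o_n, o_t, fg, bg, block_neurons=6, block_bins=8):
    """Four blocks = 2 neuron groups x 2 time intervals, centred, with the
    groups sharing o_n neurons and the intervals o_t bins."""
    span_n = 2 * block_neurons - o_n
    span_t = 2 * block_bins - o_t
    if span_n > n_neurons or span_t > n_bins:
        raise ValueError("blocks exceed (T, N) bounds for this overlap level")
    n0 = (n_neurons - span_n) // 2
    t0 = (n_bins - span_t) // 2
    groups = [(n0, n0 + block_neurons), (n0 + block_neurons - o_n, n0 + span_n)]
    intervals = [(t0, t0 + block_bins), (t0 + block_bins - o_t, t0 + span_t)]
    return [
        _block(n_bins, n_neurons, iv, g, fg, bg)
        for iv in intervals
        for g in groups
    ]


def make_block_patterns(
    preset: str,
    *,
    n_neurons: int = 20,
    n_bins: int = 30,
    bin_width: float = 10.0,
    foreground_rate: float = 300.0,
    background_rate: float = 2.0,
    overlap_level: int = 0,
) -> RatePatternSet:
    """Construct a ground-truth :class:`RatePatternSet` from a named preset.

    Presets
    -------
    ``separable``
        Four space x time separable, partly overlapping blocks: two neuron
        groups (sharing 2 neurons) by two time intervals (sharing 2 bins).
        Exactly representable with 2 spatial and 2 temporal modules.
    ``sequential``
        Four non-separable patterns: each block's 6 neurons split into
        three sub-blocks of 2 neurons activating at successive 8-bin
        offsets (a staircase), at two different onset times.
    ``overlap``
        The ``separable`` layout with adjacency controlled by
        ``overlap_level`` in {0, 1, 2, 3}; block area is constant across
        levels and mean pattern overlap increases strictly with level.
    ``info_type``
        Three equal-area patterns for the space/time shuffling control:
        pattern 0 is unique in both its neurons and its timing, pattern 1
        shares its timing with pattern 0 (information in space only), and
        pattern 2 shares its neurons with pattern 0 (information in time
        only).
    """
    fg, bg = float(foreground_rate), float(background_rate)
    if preset == "separable":
        patterns = _grid_blocks(n_bins, n_neurons, 2, 2, fg, bg)
    elif preset == "overlap":
        if overlap_level not in OVERLAP_LEVELS:
            raise ValueError(f"overlap_level must be in {sorted(OVERLAP_LEVELS)}")
        o_n, o_t = OVERLAP_LEVELS[overlap_level]
        patterns = _grid_blocks(n_bins, n_neurons, o_n, o_t, fg, bg)
    elif preset == "sequential":
        span_n = 10  # two groups of 6 neurons sharing 2
        n0 = (n_neurons - span_n) // 2
        groups = [(n0, n0 + 6), (n0 + 4, n0 + 10)]
        onsets = [0, n_bins - 24]
        patterns = []
        for t0 in onsets:
            for g0, _ in groups:
                p = np.full((n_bins, n_neurons), bg, dtype=float)
                for j in range(3):  # staircase of 2-neuron sub-blocks
                    p[t0 + 8 * j : t0 + 8 * (j + 1), g0 + 2 * j : g0 + 2 * (j + 1)] = fg
                patterns.append(p)
    elif preset == "info_type":
        patterns = [
            _block(n_bins, n_neurons, (4, 12), (2, 8), fg, bg),
            _block(n_bins, n_neurons, (4, 12), (10, 16), fg, bg),
            _block(n_bins, n_neurons, (14, 22), (2, 8), fg, bg),
        ]
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return RatePatternSet(
        patterns=patterns, background_rate=bg, bin_width=bin_width
    )


def make_mixture_patterns(
    mixture_index: int,
    *,
    n_neurons: int = 20,
    n_bins: int = 30,
    bin_width: float = 10.0,
    foreground_rate: float = 300.0,
    background_rate: float = 2.0,
):
    """Four disjoint base blocks plus one of four mixing tables.

    The observable patterns are exact non-negative sums of the base
    patterns' foreground excesses.  Returns ``(bases, mixing, observables)``
    where ``mixing`` is a (4, 4) 0/1 matrix with observables in rows.
    """
    mixings = [
        np.eye(4),
        np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]]),
        np.array([[1, 0, 0, 0], [1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]]),
        np.array([[1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]]),
    ]
    if not 0 <= mixture_index < len(mixings):
        raise ValueError(f"mixture_index must be in [0, {len(mixings)})")
    fg, bg = float(foreground_rate), float(background_rate)
    step_n = n_neurons // 4
    step_t = (n_bins - 2) // 4
    base_patterns = [
        _block(
            n_bins,
            n_neurons,
            (k * step_t, k * step_t + step_t),
            (k * step_n, k * step_n + step_n),
            fg,
            bg,
        )
        for k in range(4)
    ]
    bases = RatePatternSet(base_patterns, background_rate=bg, bin_width=bin_width)
    mixing = np.asarray(mixings[mixture_index], dtype=float)
    excess = np.stack(bases.foreground_excess())
    observables = RatePatternSet(
        [bg + np.tensordot(row, excess, axes=1) for row in mixing],
        background_rate=bg,
        bin_width=bin_width,
    )
    return bases, mixing, observables


def pattern_snr(patterns: RatePatternSet) -> np.ndarray:
    """Per-pattern SNR: peak foreground rate over background rate."""
    if patterns.background_rate <= 0:
        raise ValueError("background rate must be positive to define SNR")
    return np.array(
        [p.max() / patterns.background_rate for p in patterns.patterns]
    )


def pattern_overlap(patterns: RatePatternSet) -> float:
    """Mean pairwise geodesic similarity of foreground patterns, in percent.

    Computed on the background-subtracted rate maps, so disjoint-support
    patterns have overlap 0 regardless of the background rate, and uniform
    rescaling of the foreground (i.e. the SNR) leaves the value unchanged.
    """
    if patterns.n_patterns < 2:
        raise ValueError("pattern overlap needs at least two patterns")
    excess = patterns.foreground_excess()
    sims = [
        geodesic_similarity(excess[i], excess[j])
        for i, j in combinations(range(patterns.n_patterns), 2)
    ]
    return float(100.0 * np.mean(sims))


def _trial_rate(patterns, active, mode):
    bg = patterns.background_rate
    rate = np.full((patterns.n_bins, patterns.n_neurons), bg)
    if mode == "max":
        for k in active:
            rate = np.maximum(rate, patterns.patterns[k])
    elif mode == "add":
        for k, ex in zip(range(patterns.n_patterns), patterns.foreground_excess()):
            if k in active:
                rate = rate + ex
    else:
        raise ValueError(f"unknown superposition mode {mode!r}")
    return rate


def generate_trials(
    patterns: RatePatternSet,
    design: PresenceDesign,
    n_trials: int,
    seed,
    superposition: str = "add",
) -> TrialTensor:
    """Draw Poisson spike-count trials from the ground-truth patterns.

    Parameters
    ----------
    patterns, design
        The rate patterns and the per-trial presence rule.
    n_trials : int
        Total number of trials in ``independent_mixture`` mode; trials per
        stimulus in ``fixed_conditions`` mode.
    seed : int or numpy Generator
        Source of randomness; fixed seed gives a bit-identical tensor.
    superposition : {"add", "max"}
        Rule for co-active overlapping patterns.  The default adds the
        foreground excesses on top of the background, which is the rate of
        the superposition of independent Poisson processes, one per
        pattern.  "max" takes the element-wise maximum of the rate maps
        instead, keeping the SNR of overlap regions constant.

    Counts in each bin are Poisson with mean ``rate_Hz * bin_width_ms/1000``.
    """
    if n_trials < 1:
        raise ValueError("at least one trial is required")
    rng = np.random.default_rng(seed)
    dt_s = patterns.bin_width / 1000.0

    rates = []
    labels = []
    if design.mode == "independent_mixture":
        present = rng.random((n_trials, patterns.n_patterns)) < (
            design.presence_probability
        )
        for trial in range(n_trials):
            active = np.flatnonzero(present[trial])
            rates.append(_trial_rate(patterns, set(active), superposition))
            labels.append("".join("1" if p else "0" for p in present[trial]))
    else:
        for label, subset in design.condition_table.items():
            rate = _trial_rate(patterns, set(subset), superposition)
            for _ in range(n_trials):
                rates.append(rate)
                labels.append(label)

    rates = np.stack(rates)
    counts = rng.poisson(rates * dt_s)
    return TrialTensor(
        counts=counts,
        bin_width=patterns.bin_width,
        window=(0.0, patterns.n_bins * patterns.bin_width),
        labels=np.asarray(labels),
    )
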