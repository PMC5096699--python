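"""Permutation procedures isolating spatial, temporal and latency information.

A population code can carry stimulus information in space (which neurons
fire and how much), in time (when they fire), or inseparably in both.
Shuffling single-trial responses along one dimension destroys the
information specific to that dimension while conserving the other:

* ``shuffle_time`` permutes time bins within each trial (space-only
  condition: per-neuron trial totals are conserved exactly),
* ``shuffle_space`` permutes neuron identities within each trial
  (time-only condition: per-bin pooled population counts are conserved),
* ``first_spike_filter`` keeps only each neuron's first spike per trial
  (latency code),
* ``coarsen_precision`` permutes bins within non-overlapping groups of k
  consecutive bins, reducing the effective temporal precision to
  k * bin_width while conserving per-group counts.

``space_time_report`` runs the full decoding pipeline under each requested
condition (shuffles applied to the data before module fitting, on training
and test partitions alike) and tabulates accuracies and their differences
from the unshuffled space-and-time condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import TrialTensor, as_event_table, bin_spikes
from .decoding import decode_pipeline

CONDITIONS = ("space_and_time", "space_only", "time_only")


def shuffle_time(
    tensor: TrialTensor, seed=None, per_neuron: bool = False
) -> TrialTensor:
    """Permute time bins within each trial (destroys timing information).

    By default one permutation per trial is applied jointly to all neurons,
    which destroys only temporal order while leaving within-bin spatial
    patterns intact; ``per_neuron`` draws an independent permutation for
    every neuron.  Per-trial per-neuron total counts are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    counts = tensor.counts.copy()
    for s in range(tensor.n_trials):
        if per_neuron:
            for n in range(tensor.n_neurons):
                counts[s, :, n] = counts[s, rng.permutation(tensor.n_bins), n]
        else:
            counts[s] = counts[s, rng.permutation(tensor.n_bins), :]
    return tensor.with_counts(counts)


def shuffle_space(
    tensor: TrialTensor, seed=None, per_bin: bool = False
) -> TrialTensor:
    """Permute neuron identities within each trial (destroys spatial info).

    By default one permutation per trial is applied jointly to all bins;
    ``per_bin`` draws an independent permutation for every bin.  Per-trial
    per-bin pooled population counts are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    counts = tensor.counts.copy()
    for s in range(tensor.n_trials):
        if per_bin:
            for t in range(tensor.n_bins):
                counts[s, t, :] = counts[s, t, rng.permutation(tensor.n_neurons)]
        else:
            counts[s] = counts[s][:, rng.permutation(tensor.n_neurons)]
    return tensor.with_counts(counts)


def first_spike_filter(events) -> pd.DataFrame:
    """Keep only the earliest spike of each neuron in each trial.

    Idempotent; silent neurons stay silent.  The returned table has the
    same columns as the input.
    """
    table = as_event_table(events)
    first = table.loc[
        table.groupby(["trial", "neuron"])["time_ms"].idxmin()
    ]
    return first.sort_values(["trial", "neuron"]).reset_index(drop=True)


def coarsen_precision(
    tensor: TrialTensor, k: int, seed=None, per_neuron: bool = True
) -> TrialTensor:
    """Shuffle bins within groups of k consecutive bins.

    Reduces the effective temporal precision from ``bin_width`` to
    ``k * bin_width`` while conserving per-trial per-neuron counts inside
    every group.  ``k`` must divide the number of bins; ``k = 1`` is the
    identity.  By default permutations are drawn independently per neuron
    (and per trial and group); ``per_neuron=False`` applies one
    permutation per group jointly to all neurons.
    """
    if k < 1:
        raise ValueError("group size k must be >= 1")
    if tensor.n_bins % k != 0:
        raise ValueError(
            f"group size {k} does not divide {tensor.n_bins} bins; trim the "
            "window to a multiple of k first"
        )
    if k == 1:
        return tensor.with_counts(tensor.counts.copy())
    rng = np.random.default_rng(seed)
    counts = tensor.counts.copy()
    n_groups = tensor.n_bins // k
    for s in range(tensor.n_trials):
        for g in range(n_groups):
            sl = slice(g * k, (g + 1) * k)
            if per_neuron:
                for n in range(tensor.n_neurons):
                    perm = rng.permutation(k)
                    counts[s, sl, n] = counts[s, sl, n][perm]
            else:
                perm = rng.permutation(k)
                counts[s, sl, :] = counts[s, sl, :][perm]
    return tensor.with_counts(counts)


def subsample_population(
    tensor: TrialTensor, fraction: float, seed=None
) -> TrialTensor:
    """Random neuron subset of the given fraction (at least one neuron)."""
    if not 0 < fraction <= 1:
        raise ValueError("population fraction must be in (0, 1]")
    if fraction == 1.0:
        return tensor
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(fraction * tensor.n_neurons)))
    keep = np.sort(rng.choice(tensor.n_neurons, size=n_keep, replace=False))
    return tensor.select_neurons(keep)


def space_time_report(
    tensor: TrialTensor,
    model: str,
    counts,
    *,
    n_train: int,
    seed=None,
    conditions=CONDITIONS,
    precision_groups=(),
    population_fractions=(),
    n_population_repeats: int = 3,
    events=None,
    fit_opts: dict | None = None,
) -> pd.DataFrame:
    """Decoding accuracy under shuffling conditions, with deltas.

    Runs :func:`~popfactor.decoding.decode_pipeline` on the unshuffled
    data (``space_and_time``) and under each requested condition:
    ``space_only`` (time-shuffled), ``time_only`` (space-shuffled),
    ``latency`` (first-spike-filtered; requires the raw ``events`` table),
    ``precision(k)`` for each k in ``precision_groups``, and
    ``population_fraction(f)`` for each f in ``population_fractions``
    (averaged over random neuron subsets).  Shuffles are applied to the
    full dataset before splitting, so train and test partitions see the
    same manipulation.  The ``delta`` column is the accuracy drop from the
    ``space_and_time`` condition.
    """
    seq = np.random.SeedSequence(seed)
    seeds = iter(
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in seq.spawn(256)
    )
    pipe_seed = next(seeds)

    def run(data) -> float:
        return decode_pipeline(
            data, model, counts, n_train=n_train, seed=pipe_seed,
            fit_opts=fit_opts,
        ).accuracy

    rows = []
    base = run(tensor)
    rows.append(("space_and_time", base))
    for condition in conditions:
        if condition == "space_and_time":
            continue
        if condition == "space_only":
            rows.append((condition, run(shuffle_time(tensor, next(seeds)))))
        elif condition == "time_only":
            rows.append((condition, run(shuffle_space(tensor, next(seeds)))))
        elif condition == "latency":
            if events is None:
                raise ValueError("latency condition requires the event table")
            filtered = bin_spikes(
                first_spike_filter(events),
                tensor.bin_width,
                tensor.window,
                n_neurons=tensor.n_neurons,
            )
            rows.append((condition, run(filtered)))
        else:
            raise ValueError(f"unknown condition {condition!r}")
    for k in precision_groups:
        rows.append(
            (f"precision({k})", run(coarsen_precision(tensor, k, next(seeds))))
        )
    for f in population_fractions:
        accs = [
            run(subsample_population(tensor, f, next(seeds)))
            for _ in range(n_population_repeats if f < 1.0 else 1)
        ]
        rows.append((f"population_fraction({f})", float(np.mean(accs))))

    report = pd.DataFrame(rows, columns=["condition", "accuracy"])
    report["delta"] = base - report["accuracy"]
    return report
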