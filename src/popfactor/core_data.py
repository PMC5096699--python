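"""Trial-structured spike data: binning, matricization, and HDF5 I/O.

The central container is :class:`TrialTensor`, a non-negative spike-count
array of shape (trials, time bins, neurons) together with the bin width,
the analysis window relative to stimulus onset, and one stimulus label per
trial.  Every decomposition in this package consumes a ``TrialTensor``.

Spike events come in as a flat table with columns ``trial``, ``stimulus``,
``neuron``, ``time_ms``.  Binning uses 0-based, half-open bins
[t, t + bin_width); a spike exactly at the window end falls outside the
window and is dropped (the count of dropped events is reported on the
returned tensor).

Two matricizations are used throughout:

* spatiotemporal: (S, T*N), each row a trial flattened time-major (all
  neurons of bin 0, then bin 1, ...),
* spatial: (S*T, N), rows ordered trial-major then bin.

Both are exact bijections; the inverse reshapes are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

EVENT_COLUMNS = ("trial", "stimulus", "neuron", "time_ms")


@dataclass
class TrialTensor:
    """Binned population spike counts for a set of trials.

    Attributes
    ----------
    counts : ndarray, shape (S, T, N)
        Non-negative integer spike counts per trial, time bin and neuron.
    bin_width : float
        Bin width in ms.
    window : tuple of float
        (start_ms, end_ms) of the analysis window relative to stimulus onset.
    labels : ndarray, shape (S,)
        One stimulus label per trial (opaque categoricals, no order assumed).
    n_dropped_events : int
        Number of spike events outside the window discarded during binning.
    """

    counts: np.ndarray
    bin_width: float
    window: tuple[float, float]
    labels: np.ndarray
    n_dropped_events: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.labels = np.asarray(self.labels)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (trials, bins, neurons)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        start, end = self.window
        if not end > start:
            raise ValueError("window start must precede window end")
        n_bins = (end - start) / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9 or round(n_bins) != self.n_bins:
            raise ValueError(
                f"window length {end - start} ms is not {self.n_bins} bins "
                f"of {self.bin_width} ms"
            )
        if len(self.labels) != self.n_trials:
            raise ValueError("labels must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def select_trials(self, indices: np.ndarray) -> "TrialTensor":
        """Return a new tensor restricted to the given trial indices."""
        indices = np.asarray(indices)
        return replace(
            self, counts=self.counts[indices], labels=self.labels[indices]
        )

    def select_neurons(self, indices: np.ndarray) -> "TrialTensor":
        """Return a new tensor restricted to the given neuron indices."""
        indices = np.asarray(indices)
        return replace(self, counts=self.counts[:, :, indices])

    def with_counts(self, counts: np.ndarray) -> "TrialTensor":
        """Return a copy with ``counts`` replaced (same metadata)."""
        return replace(self, counts=counts)


def as_event_table(events) -> pd.DataFrame:
    """Coerce ``events`` to a spike-event DataFrame and validate its schema."""
    table = pd.DataFrame(events)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    return table


def read_events(path) -> pd.DataFrame:
    """Read a spike-event table from delimited text (CSV or TSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return as_event_table(pd.read_csv(path, sep=sep))


def write_events(table: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    as_event_table(table).to_csv(path, sep=sep, index=False)


def bin_spikes(
    events,
    bin_width: float,
    window: tuple[float, float],
    n_neurons: int | None = None,
) -> TrialTensor:
    """Bin spike events into a :class:`TrialTensor`.

    Parameters
    ----------
    events : DataFrame-like
        Columns ``trial``, ``stimulus``, ``neuron``, ``time_ms``.
    bin_width : float
        Bin width in ms; must divide the window length exactly.
    window : (float, float)
        Analysis window (start_ms, end_ms) relative to stimulus onset.
    n_neurons : int, optional
        Population size N.  Defaults to ``max(neuron) + 1``; neuron indices
        must be dense in [0, N).

    Events outside [start, end) are dropped; their count is recorded on
    ``n_dropped_events``.  In-window spikes are conserved exactly:
    ``tensor.counts.sum()`` equals the number of in-window events.
    """
    table = as_event_table(events)
    start, end = window
    if not end > start:
        raise ValueError("window start must precede window end")
    n_bins_f = (end - start) / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError(
            f"bin width {bin_width} ms does not divide window length "
            f"{end - start} ms"
        )

    neurons = table["neuron"].to_numpy()
    if len(neurons) > 0:
        if np.any(neurons < 0):
            raise ValueError("neuron indices must be non-negative")
        observed = np.unique(neurons)
        inferred_n = int(observed.max()) + 1
        if n_neurons is None:
            n_neurons = inferred_n
            missing = np.setdiff1d(np.arange(n_neurons), observed)
            if missing.size:
                raise ValueError(
                    f"neuron indices are not dense in [0, {n_neurons}): "
                    f"missing {missing.tolist()}"
                )
        elif inferred_n > n_neurons:
            raise ValueError(
                f"neuron index {observed.max()} exceeds population size "
                f"{n_neurons}"
            )
    elif n_neurons is None:
        raise ValueError("n_neurons is required for an empty event table")

    # one stimulus label per trial; trials ordered by trial index
    per_trial = table.drop_duplicates("trial").sort_values("trial")
    if per_trial["trial"].size != table.groupby("trial")["stimulus"].nunique().size or (
        table.groupby("trial")["stimulus"].nunique() > 1
    ).any():
        bad = table.groupby("trial")["stimulus"].nunique()
        raise ValueError(
            f"trials with multiple stimulus labels: "
            f"{bad.index[bad > 1].tolist()}"
        )
    trial_ids = per_trial["trial"].to_numpy()
    labels = per_trial["stimulus"].to_numpy()
    trial_pos = {t: i for i, t in enumerate(trial_ids)}

    counts = np.zeros((len(trial_ids), n_bins, n_neurons), dtype=np.int64)
    times = table["time_ms"].to_numpy(dtype=float)
    in_window = (times >= start) & (times < end)
    n_dropped = int((~in_window).sum())
    sub = table.loc[in_window]
    bins = ((sub["time_ms"].to_numpy(dtype=float) - start) // bin_width).astype(int)
    rows = np.fromiter(
        (trial_pos[t] for t in sub["trial"].to_numpy()), dtype=int, count=len(sub)
    )
    np.add.at(counts, (rows, bins, sub["neuron"].to_numpy(dtype=int)), 1)

    return TrialTensor(
        counts=counts,
        bin_width=float(bin_width),
        window=(float(start), float(end)),
        labels=labels,
        n_dropped_events=n_dropped,
    )


def matricize_spatiotemporal(tensor: TrialTensor) -> np.ndarray:
    """Flatten to (S, T*N) with time-major row ordering."""
    s, t, n = tensor.shape
    return tensor.counts.reshape(s, t * n)


def tensorize_spatiotemporal(
    matrix: np.ndarray, n_bins: int, n_neurons: int
) -> np.ndarray:
    """Inverse of :func:`matricize_spatiotemporal`; returns (S, T, N)."""
    matrix = np.asarray(matrix)
    return matrix.reshape(matrix.shape[0], n_bins, n_neurons)


def matricize_spatial(tensor: TrialTensor) -> np.ndarray:
    """Flatten to (S*T, N) with (trial, bin)-major row ordering."""
    s, t, n = tensor.shape
    return tensor.counts.reshape(s * t, n)


def tensorize_spatial(
    matrix: np.ndarray, n_trials: int, n_bins: int
) -> np.ndarray:
    """Inverse of :func:`matricize_spatial`; returns (S, T, N)."""
    matrix = np.asarray(matrix)
    return matrix.reshape(n_trials, n_bins, matrix.shape[1])


# ---------------------------------------------------------------------------
# HDF5 array container


def save_container(path, arrays: dict, meta: dict | None = None) -> None:
    """Write named arrays plus metadata to an HDF5 file (bit-exact round trip).

    Arrays go to datasets under the root group; metadata to root attributes.
    String-labelled arrays are stored with an h5py variable-length dtype.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for name, arr in arrays.items():
            arr = np.asarray(arr)
            if arr.dtype.kind in ("U", "O"):
                f.create_dataset(
                    name, data=arr.astype(object), dtype=h5py.string_dtype()
                )
            else:
                f.create_dataset(name, data=arr)
        for key, value in (meta or {}).items():
            f.attrs[key] = value


def load_container(path, required: tuple[str, ...] = ()) -> tuple[dict, dict]:
    """Load (arrays, meta) written by :func:`save_container`.

    Raises on schema-version mismatch and on any missing ``required``
    metadata key (the error names the key).
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"container schema version {version!r} does not match "
                f"expected {SCHEMA_VERSION}"
            )
        arrays = {}
        for name, dataset in f.items():
            data = dataset[()]
            if h5py.check_string_dtype(dataset.dtype):
                data = np.asarray(
                    [x.decode() if isinstance(x, bytes) else x for x in data]
                )
            arrays[name] = data
        meta = {k: v for k, v in f.attrs.items() if k != "schema_version"}
    for key in required:
        if key not in meta:
            raise KeyError(f"container is missing required metadata key {key!r}")
    return arrays, meta


def save_tensor(path, tensor: TrialTensor, **extra_meta) -> None:
    """Save a :class:`TrialTensor` to HDF5."""
    save_container(
        path,
        arrays={"counts": tensor.counts, "labels": tensor.labels},
        meta={
            "bin_width": tensor.bin_width,
            "window_start": tensor.window[0],
            "window_end": tensor.window[1],
            **extra_meta,
        },
    )


def load_tensor(path) -> TrialTensor:
    """Load a :class:`TrialTensor` saved by :func:`save_tensor`."""
    arrays, meta = load_container(
        path, required=("bin_width", "window_start", "window_end")
    )
    for key in ("counts", "labels"):
        if key not in arrays:
            raise KeyError(f"container is missing required array {key!r}")
    return TrialTensor(
        counts=arrays["counts"],
        bin_width=float(meta["bin_width"]),
        window=(float(meta["window_start"]), float(meta["window_end"])),
        labels=arrays["labels"],
    )
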