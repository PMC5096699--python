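"""Stimulus decoding from single-trial activation coefficients.

The decoding pipeline mirrors the standard train/test procedure for
module-based population decoding: modules are fit on training trials only,
activation coefficients of held-out trials are inferred with the modules
frozen, zero-variance coefficients (measured on the training set) are
dropped, and a multiclass linear discriminant analysis (LDA) classifier
with pooled within-class covariance predicts the stimulus label of each
test trial.  Accuracy is the percentage of correct predictions on the
test set.

The number of modules can be selected by leave-one-out cross-validation
within the training set: for every candidate count, one trial per stimulus
is held out as validation, modules are fit on the rest, and the candidate
with the highest average validation accuracy is chosen; ties are broken
toward the smallest total number of modules (then smallest temporal count,
then smallest spatial count).

A rank-order decoder over first-spike latencies is included as a
module-free baseline: neurons are ranked by latency within each trial
(silent neurons share the maximal rank, ties get average ranks), each
stimulus gets the mean training rank vector as template, and test trials
are assigned to the template with the highest rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core_data import TrialTensor, as_event_table, matricize_spatiotemporal
from . import matrix_decomp as md
from . import tensor_decomp as td

# small always-on shrinkage toward the scaled identity keeps the pooled
# covariance invertible (raw LDA on T*N features is otherwise singular)
LDA_SHRINKAGE = 1e-6

MATRIX_MODELS = ("st-nmf", "st-pca", "st-ica", "st-fa")
TENSOR_MODELS = ("sbt-nmf", "tucker2")
MODELS = TENSOR_MODELS + MATRIX_MODELS


@dataclass
class DecodingResult:
    """Outcome of one decoding experiment."""

    accuracy: float  # percent correct on the test set
    confusion: np.ndarray  # rows: true class, cols: predicted
    class_labels: np.ndarray
    model: str | None = None
    selected_counts: tuple | None = None
    n_train_per_stimulus: int | None = None
    n_test_per_stimulus: int | None = None
    seed: int | None = None
    dropped_features: np.ndarray = field(default_factory=lambda: np.array([], int))


def train_test_split(
    tensor: TrialTensor, n_train: int, seed
) -> tuple[TrialTensor, TrialTensor]:
    """Stratified random split with ``n_train`` trials per stimulus in train.

    The remaining trials of each stimulus form the test set.  Every
    stimulus must have at least ``n_train + 1`` trials; the split is
    reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    labels = tensor.labels
    train_idx, test_idx = [], []
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        if len(idx) < n_train + 1:
            raise ValueError(
                f"stimulus {label!r} has {len(idx)} trials; "
                f"need at least {n_train + 1} for a {n_train}-trial train split"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return (
        tensor.select_trials(np.sort(train_idx)),
        tensor.select_trials(np.sort(test_idx)),
    )


def lda_decode(
    train_coeffs, train_labels, test_coeffs, test_labels
) -> DecodingResult:
    """Multiclass LDA decoding of stimulus labels from coefficients.

    Coefficients with zero variance across all training trials are removed
    from train and test before fitting.  The pooled within-class covariance
    is lightly ridge-regularized so the classifier is defined even for
    singular (e.g. high-dimensional raw-count) predictors.
    """
    Xtr = np.asarray(train_coeffs, dtype=float)
    Xte = np.asarray(test_coeffs, dtype=float)
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    classes, counts = np.unique(ytr, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA decoding requires at least two stimulus classes")
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(
            f"classes with a single training trial cannot be decoded: "
            f"{bad.tolist()}"
        )
    variances = Xtr.var(axis=0)
    keep = variances > 0
    dropped = np.flatnonzero(~keep)
    if not np.any(keep):
        raise ValueError("all coefficients have zero variance on the training set")
    Xtr = Xtr[:, keep]
    Xte = Xte[:, keep]

    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=LDA_SHRINKAGE)
    clf.fit(Xtr, ytr)
    predictions = clf.predict(Xte)

    all_classes = np.unique(np.concatenate([classes, np.unique(yte)]))
    index = {c: i for i, c in enumerate(all_classes)}
    confusion = np.zeros((len(all_classes), len(all_classes)), dtype=int)
    for truth, pred in zip(yte, predictions):
        confusion[index[truth], index[pred]] += 1
    accuracy = 100.0 * float(np.mean(predictions == yte))
    return DecodingResult(
        accuracy=accuracy,
        confusion=confusion,
        class_labels=all_classes,
        dropped_features=dropped,
    )


def raw_lda(train: TrialTensor, test: TrialTensor) -> DecodingResult:
    """LDA on the flattened spike-count vectors, without any decomposition."""
    result = lda_decode(
        matricize_spatiotemporal(train),
        train.labels,
        matricize_spatiotemporal(test),
        test.labels,
    )
    result.model = "raw-lda"
    return result


# ---------------------------------------------------------------------------
# model fitting / coefficient inference dispatch


def _check_counts(model: str, counts) -> tuple:
    if model in TENSOR_MODELS:
        p, l = counts
        return int(p), int(l)
    (k,) = counts if isinstance(counts, (tuple, list, np.ndarray)) else (counts,)
    return (int(k),)


def fit_model(train: TrialTensor, model: str, counts, seed=None, **opts):
    """Fit the requested decomposition on the training tensor."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    counts = _check_counts(model, counts)
    if model == "sbt-nmf":
        return td.space_by_time_nmf(train, *counts, seed=seed, **opts)
    if model == "tucker2":
        return td.orthogonal_tucker2(train, *counts)
    if model == "st-nmf":
        return md.spatiotemporal_nmf(train, counts[0], seed=seed, **opts)
    return md.spatiotemporal_linear(train, counts[0], model[3:], seed=seed)


def model_coefficients(decomp, tensor: TrialTensor, seed=None) -> np.ndarray:
    """Per-trial coefficient vectors for ``tensor`` under frozen modules."""
    if isinstance(decomp, td.SbTDecomposition):
        core = td.infer_core(decomp, tensor, seed=seed)
        return core.reshape(tensor.n_trials, -1)
    return md.infer_activations(decomp, tensor, seed=seed)


def training_coefficients(decomp, train: TrialTensor) -> np.ndarray:
    """Coefficients of the training trials as fitted (no re-inference)."""
    if isinstance(decomp, td.SbTDecomposition):
        return decomp.core.reshape(train.n_trials, -1)
    return decomp.activations


# ---------------------------------------------------------------------------
# module-count selection


def default_grid(model: str, max_p: int = 4, max_l: int = 4, max_k: int = 6):
    """Candidate module counts: (P, L) pairs or (K,) singletons."""
    if model in TENSOR_MODELS:
        return [
            (p, l) for p, l in product(range(1, max_p + 1), range(1, max_l + 1))
        ]
    return [(k,) for k in range(1, max_k + 1)]


def _loo_folds(labels: np.ndarray):
    """Leave one trial per stimulus out; yields validation index arrays."""
    classes = np.unique(labels)
    per_class = [np.flatnonzero(labels == c) for c in classes]
    n_folds = min(len(idx) for idx in per_class)
    for fold in range(n_folds):
        yield np.array([idx[fold] for idx in per_class])


def select_module_numbers(
    train: TrialTensor,
    model: str,
    grid=None,
    seed=None,
    fit_opts: dict | None = None,
) -> tuple:
    """Leave-one-out cross-validated selection of module counts.

    For each candidate in ``grid``, one trial per stimulus is held out as
    validation; modules are fit on the remaining training trials,
    validation coefficients inferred, and LDA accuracy recorded.  The
    candidate with the maximum average validation accuracy is returned;
    ties are broken by the minimum sum of module counts, then by the
    smallest leading count.

    ``fit_opts`` tunes the per-fold fits; the default uses fewer restarts
    and a looser tolerance than a final fit since selection only ranks
    candidates.
    """
    if grid is None:
        grid = default_grid(model)
    grid = [tuple(c) for c in grid]
    if not grid:
        raise ValueError("candidate grid must be non-empty")
    classes, class_counts = np.unique(train.labels, return_counts=True)
    if class_counts.min() < 3:
        raise ValueError(
            "leave-one-out selection needs at least 3 training trials per stimulus"
        )
    if model in ("st-nmf", "sbt-nmf"):
        opts = {"n_restarts": 2, "max_iter": 300, "tol": 1e-5}
        opts.update(fit_opts or {})
    else:
        opts = dict(fit_opts or {})
    rng = np.random.default_rng(seed)

    folds = list(_loo_folds(train.labels))
    all_idx = np.arange(train.n_trials)
    scores = np.zeros(len(grid))
    for val_idx in folds:
        fit_idx = np.setdiff1d(all_idx, val_idx)
        fit_tensor = train.select_trials(fit_idx)
        val_tensor = train.select_trials(val_idx)
        for gi, counts in enumerate(grid):
            fold_seed = int(rng.integers(0, 2**31 - 1))
            decomp = fit_model(fit_tensor, model, counts, seed=fold_seed, **opts)
            try:
                result = lda_decode(
                    training_coefficients(decomp, fit_tensor),
                    fit_tensor.labels,
                    model_coefficients(decomp, val_tensor, seed=fold_seed),
                    val_tensor.labels,
                )
                scores[gi] += result.accuracy
            except ValueError:
                pass  # e.g. all-zero-variance coefficients: score 0 for fold
    scores /= len(folds)

    best = scores.max()
    tied = [grid[i] for i in np.flatnonzero(np.isclose(scores, best))]
    tied.sort(key=lambda c: (sum(c),) + tuple(c))
    return tied[0]


# ---------------------------------------------------------------------------
# end-to-end pipelines


def decode_pipeline(
    tensor: TrialTensor,
    model: str,
    counts="auto",
    *,
    n_train: int,
    seed=None,
    grid=None,
    fit_opts: dict | None = None,
    selection_fit_opts: dict | None = None,
) -> DecodingResult:
    """Split, fit modules on training trials only, decode the test set.

    ``counts`` may be explicit module counts or ``"auto"`` to run
    leave-one-out selection on the training set first.  Test coefficients
    are always obtained by frozen-module inference, so no information
    flows from the test set into the modules, the zero-variance mask or
    the classifier.
    """
    seq = np.random.SeedSequence(seed)
    split_seed, sel_seed, fit_seed = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in seq.spawn(3)
    ]
    train, test = train_test_split(tensor, n_train, split_seed)
    if isinstance(counts, str) and counts == "auto":
        counts = select_module_numbers(
            train, model, grid=grid, seed=sel_seed, fit_opts=selection_fit_opts
        )
    decomp = fit_model(train, model, counts, seed=fit_seed, **(fit_opts or {}))
    result = lda_decode(
        training_coefficients(decomp, train),
        train.labels,
        model_coefficients(decomp, test, seed=fit_seed),
        test.labels,
    )
    result.model = model
    result.selected_counts = _check_counts(model, counts)
    result.n_train_per_stimulus = n_train
    result.n_test_per_stimulus = test.n_trials // len(np.unique(test.labels))
    result.seed = seed
    return result


def generalization_experiment(
    tensor: TrialTensor,
    model: str,
    counts,
    n_module_stimuli,
    *,
    n_train: int,
    set_b_size: int | None = None,
    seed=None,
    fit_opts: dict | None = None,
) -> dict:
    """Decode stimuli whose responses never contributed to the modules.

    Stimuli are split into a module-training pool B (``set_b_size`` of
    them; the rest form the evaluation set A).  For each requested n in
    ``n_module_stimuli``: modules are fit on the training trials of n
    stimuli drawn from B, coefficients are inferred for all set-A trials,
    and an LDA classifier is trained on set-A training trials and scored
    on set-A test trials.  Returns {n: DecodingResult}.

    With ``set_b_size`` equal to the total number of stimuli, sets A and B
    coincide and n = all stimuli reduces to the standard pipeline.
    """
    if np.isscalar(n_module_stimuli):
        n_module_stimuli = [int(n_module_stimuli)]
    seq = np.random.SeedSequence(seed)
    pool_seed, split_seed, fit_seed = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in seq.spawn(3)
    ]
    stimuli = np.unique(tensor.labels)
    if set_b_size is None:
        set_b_size = min(10, len(stimuli))
    rng = np.random.default_rng(pool_seed)
    order = rng.permutation(len(stimuli))
    set_b = stimuli[order[:set_b_size]]
    set_a = stimuli if set_b_size >= len(stimuli) else stimuli[order[set_b_size:]]

    train, test = train_test_split(tensor, n_train, split_seed)
    a_train = train.select_trials(np.flatnonzero(np.isin(train.labels, set_a)))
    a_test = test.select_trials(np.flatnonzero(np.isin(test.labels, set_a)))

    results = {}
    for n in n_module_stimuli:
        if n > len(set_b):
            raise ValueError(
                f"{n} module-training stimuli requested but set B has "
                f"{len(set_b)}"
            )
        chosen = set_b[:n]
        b_train = train.select_trials(
            np.flatnonzero(np.isin(train.labels, chosen))
        )
        decomp = fit_model(
            b_train, model, counts, seed=fit_seed, **(fit_opts or {})
        )
        result = lda_decode(
            model_coefficients(decomp, a_train, seed=fit_seed),
            a_train.labels,
            model_coefficients(decomp, a_test, seed=fit_seed),
            a_test.labels,
        )
        result.model = model
        result.selected_counts = _check_counts(model, counts)
        result.n_train_per_stimulus = n_train
        result.seed = seed
        results[int(n)] = result
    return results


# ---------------------------------------------------------------------------
# rank-order decoding of first-spike latencies


def first_spike_latencies(events, n_neurons: int | None = None):
    """Per-trial first-spike latency matrix (S, N); silent neurons get +inf.

    Returns ``(latencies, labels)`` with trials ordered by trial index.
    """
    table = as_event_table(events)
    trials = np.sort(table["trial"].unique())
    if n_neurons is None:
        n_neurons = int(table["neuron"].max()) + 1
    lat = np.full((len(trials), n_neurons), np.inf)
    pos = {t: i for i, t in enumerate(trials)}
    firsts = table.groupby(["trial", "neuron"])["time_ms"].min()
    for (trial, neuron), time in firsts.items():
        lat[pos[trial], int(neuron)] = time
    labels = (
        table.drop_duplicates("trial").sort_values("trial")["stimulus"].to_numpy()
    )
    return lat, labels


def _rank_vector(latencies: np.ndarray) -> np.ndarray:
    # rankdata places +inf (silent) last; average ranks for ties, so all
    # silent neurons share the maximal rank
    return rankdata(latencies, method="average")


def rank_order_decode(
    events, *, n_train: int, seed=None, n_neurons: int | None = None
) -> DecodingResult:
    """Rank-order decoding of stimuli from first-spike latencies.

    Neurons are ranked by first-spike latency within each trial; each
    stimulus' template is the mean rank vector over its training trials;
    test trials go to the template with the largest correlation between
    rank vectors (a Spearman-type statistic).  Undefined correlations
    (e.g. an all-silent test trial, whose rank vector is constant) count
    as zero, and exact ties resolve to the smallest stimulus label.
    """
    latencies, labels = first_spike_latencies(events, n_neurons=n_neurons)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    train_idx, test_idx = [], []
    for label in classes:
        idx = np.flatnonzero(labels == label)
        if len(idx) < n_train + 1:
            raise ValueError(
                f"stimulus {label!r} has too few trials for a "
                f"{n_train}-trial train split"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])

    ranks = np.apply_along_axis(_rank_vector, 1, latencies)
    templates = {}
    for label in classes:
        rows = [i for i in train_idx if labels[i] == label]
        if np.all(np.isinf(latencies[rows])):
            raise ValueError(
                f"all neurons are silent in every training trial of "
                f"stimulus {label!r}"
            )
        templates[label] = ranks[rows].mean(axis=0)

    def correlation(u, v):
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    predictions = []
    for i in test_idx:
        corrs = np.array(
            [correlation(ranks[i], templates[c]) for c in classes]
        )
        predictions.append(classes[int(np.argmax(corrs))])  # smallest on ties
    predictions = np.asarray(predictions)
    truth = labels[np.asarray(test_idx)]

    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predictions):
        confusion[index[t], index[p]] += 1
    return DecodingResult(
        accuracy=100.0 * float(np.mean(predictions == truth)),
        confusion=confusion,
        class_labels=classes,
        model="rank-order",
        n_train_per_stimulus=n_train,
        seed=seed,
    )
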