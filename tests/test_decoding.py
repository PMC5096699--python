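import hashlib

import numpy as np
import pandas as pd
import pytest

from popfactor import (
    PresenceDesign,
    TrialTensor,
    decode_pipeline,
    generate_trials,
    generalization_experiment,
    lda_decode,
    make_block_patterns,
    pair_conditions,
    rank_order_decode,
    raw_lda,
    select_module_numbers,
    train_test_split,
)
from popfactor.core_data import matricize_spatiotemporal


@pytest.fixture(scope="module")
def pair_tensor():
    """Six-condition (pairs-of-blocks) dataset, easy SNR, 12 trials each."""
    patterns = make_block_patterns("overlap", overlap_level=1,
                                   foreground_rate=100.0)
    design = PresenceDesign.conditions(pair_conditions(4))
    return generate_trials(patterns, design, 12, seed=21)


class TestTrainTestSplit:
    def test_15_15_split(self, pair_tensor):
        patterns = make_block_patterns("separable")
        tensor = generate_trials(
            patterns, PresenceDesign.conditions(pair_conditions(4)), 30, seed=0
        )
        train, test = train_test_split(tensor, 15, seed=1)
        for part in (train, test):
            _, counts = np.unique(part.labels, return_counts=True)
            assert np.all(counts == 15)

    def test_19_trials_split_10_9(self):
        patterns = make_block_patterns("separable")
        tensor = generate_trials(
            patterns, PresenceDesign.conditions(pair_conditions(4)), 19, seed=0
        )
        train, test = train_test_split(tensor, 10, seed=1)
        _, tr = np.unique(train.labels, return_counts=True)
        _, te = np.unique(test.labels, return_counts=True)
        assert np.all(tr == 10) and np.all(te == 9)

    def test_same_seed_identical_split(self, pair_tensor):
        a_train, a_test = train_test_split(pair_tensor, 6, seed=5)
        b_train, b_test = train_test_split(pair_tensor, 6, seed=5)
        assert np.array_equal(a_train.counts, b_train.counts)
        assert np.array_equal(a_test.counts, b_test.counts)

    def test_split_disjoint_and_exhaustive(self, pair_tensor):
        train, test = train_test_split(pair_tensor, 6, seed=5)
        assert train.n_trials + test.n_trials == pair_tensor.n_trials

    def test_insufficient_trials_names_stimulus(self, pair_tensor):
        with pytest.raises(ValueError, match="0\\+1"):
            train_test_split(pair_tensor, 12, seed=0)


class TestLdaDecode:
    def test_separable_clusters_decoded_perfectly(self):
        rng = np.random.default_rng(0)
        train = np.vstack([rng.normal(0, 0.1, (20, 2)),
                           rng.normal(5, 0.1, (20, 2))])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        test = np.vstack([rng.normal(0, 0.1, (10, 2)),
                          rng.normal(5, 0.1, (10, 2))])
        result = lda_decode(train, labels, test, labels[: len(test) * 2 : 2])
        assert result.accuracy == 100.0

    def test_accuracy_matches_analytic_bayes_rate(self):
        # two 1-D Gaussians, means 0 and 2, unit variance: Bayes accuracy
        # is Phi(1) ~ 84.13%
        from scipy.stats import norm

        rng = np.random.default_rng(1)
        n = 4000
        train = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        labels = np.array(["a"] * n + ["b"] * n)
        test = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        result = lda_decode(
            train[:, None], labels, test[:, None], labels
        )
        assert result.accuracy == pytest.approx(100 * norm.cdf(1.0), abs=1.5)

    def test_zero_variance_features_removed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0  # constant on train
        y = np.array(["a", "b", "c"] * 10)
        result = lda_decode(X, y, X, y)
        assert list(result.dropped_features) == [1]

    def test_all_zero_variance_rejected(self):
        X = np.ones((10, 2))
        y = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError, match="zero variance"):
            lda_decode(X, y, X, y)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="two stimulus classes"):
            lda_decode(X, np.array(["a"] * 10), X, np.array(["a"] * 10))

    def test_single_trial_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="single training trial"):
            lda_decode(X, y, X, y)

    def test_confusion_rows_sum_to_test_counts(self, pair_tensor):
        result = raw_lda(*train_test_split(pair_tensor, 6, seed=3))
        assert result.confusion.sum() == result.confusion.sum(axis=1).sum()
        assert np.all(result.confusion.sum(axis=1) == 6)

    def test_accuracy_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(4)
        Xtr = rng.normal(size=(40, 3)) + np.repeat([[0], [2]], 20, axis=0)
        y = np.array(["a"] * 20 + ["b"] * 20)
        Xte = rng.normal(size=(20, 3)) + np.repeat([[0], [2]], 10, axis=0)
        yte = np.array(["a"] * 10 + ["b"] * 10)
        base = lda_decode(Xtr, y, Xte, yte).accuracy
        scale = np.array([3.0, 0.2, 11.0])
        scaled = lda_decode(Xtr * scale, y, Xte * scale, yte).accuracy
        assert scaled == pytest.approx(base)


class TestRawLda:
    def test_identical_to_lda_on_matricized_input(self, pair_tensor):
        train, test = train_test_split(pair_tensor, 6, seed=3)
        direct = lda_decode(
            matricize_spatiotemporal(train), train.labels,
            matricize_spatiotemporal(test), test.labels,
        )
        wrapped = raw_lda(train, test)
        assert wrapped.accuracy == direct.accuracy
        assert np.array_equal(wrapped.confusion, direct.confusion)

    def test_high_snr_conditions_decoded_well(self, pair_tensor):
        result = raw_lda(*train_test_split(pair_tensor, 6, seed=3))
        assert result.accuracy > 80.0


class TestSelection:
    def test_single_candidate_grid_returned(self, pair_tensor):
        train, _ = train_test_split(pair_tensor, 6, seed=0)
        assert select_module_numbers(
            train, "sbt-nmf", grid=[(2, 2)], seed=0
        ) == (2, 2)

    def test_ground_truth_counts_selected_on_easy_data(self, pair_tensor):
        train, _ = train_test_split(pair_tensor, 6, seed=0)
        sel = select_module_numbers(
            train, "sbt-nmf",
            grid=[(1, 1), (2, 2), (2, 3), (3, 3)],
            seed=0,
            fit_opts={"n_restarts": 1, "max_iter": 150, "tol": 1e-4},
        )
        assert sel == (2, 2)

    def test_empty_grid_rejected(self, pair_tensor):
        train, _ = train_test_split(pair_tensor, 6, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            select_module_numbers(train, "sbt-nmf", grid=[], seed=0)


class TestDecodePipeline:
    def test_high_snr_pairs_decoded_near_perfectly(self, pair_tensor):
        result = decode_pipeline(
            pair_tensor, "sbt-nmf", (2, 2), n_train=6, seed=0
        )
        assert result.accuracy > 95.0

    def test_label_shuffle_gives_chance_level(self, pair_tensor):
        rng = np.random.default_rng(0)
        accs = []
        for s in range(3):
            shuffled = TrialTensor(
                counts=pair_tensor.counts,
                bin_width=pair_tensor.bin_width,
                window=pair_tensor.window,
                labels=rng.permutation(pair_tensor.labels),
            )
            accs.append(
                decode_pipeline(
                    shuffled, "sbt-nmf", (2, 2), n_train=6, seed=s,
                    fit_opts={"n_restarts": 1, "max_iter": 100},
                ).accuracy
            )
        chance = 100.0 / 6
        assert 0.3 * chance < np.mean(accs) < 2.5 * chance

    def test_no_test_set_leakage(self, pair_tensor):
        digest_before = hashlib.sha256(
            pair_tensor.counts.tobytes()
        ).hexdigest()
        decode_pipeline(pair_tensor, "sbt-nmf", (2, 2), n_train=6, seed=1,
                        fit_opts={"n_restarts": 1, "max_iter": 60})
        assert (
            hashlib.sha256(pair_tensor.counts.tobytes()).hexdigest()
            == digest_before
        )

    def test_single_class_rejected(self, pair_tensor):
        idx = np.flatnonzero(pair_tensor.labels == pair_tensor.labels[0])
        single = pair_tensor.select_trials(idx)
        with pytest.raises(ValueError, match="two stimulus classes"):
            decode_pipeline(single, "sbt-nmf", (2, 2), n_train=6, seed=0)


class TestGeneralization:
    def test_unseen_stimuli_decoded_above_chance(self, pair_tensor):
        results = generalization_experiment(
            pair_tensor, "sbt-nmf", (2, 2), [1, 3],
            n_train=6, set_b_size=3, seed=0,
            fit_opts={"n_restarts": 1, "max_iter": 100},
        )
        chance = 100.0 / 3  # set A has 3 held-out stimuli
        assert results[1].accuracy > 1.5 * chance
        assert results[3].accuracy >= results[1].accuracy - 15.0

    def test_all_stimuli_reduces_to_pipeline_conditions(self, pair_tensor):
        results = generalization_experiment(
            pair_tensor, "sbt-nmf", (2, 2), [6],
            n_train=6, set_b_size=6, seed=0,
            fit_opts={"n_restarts": 1, "max_iter": 100},
        )
        assert results[6].accuracy > 90.0

    def test_requesting_more_than_pool_rejected(self, pair_tensor):
        with pytest.raises(ValueError, match="set B"):
            generalization_experiment(
                pair_tensor, "sbt-nmf", (2, 2), [4],
                n_train=6, set_b_size=3, seed=0,
            )


class TestRankOrderDecoder:
    @staticmethod
    def _events(latency_rows, labels, n_trials_per=4, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        trial = 0
        for latencies, label in zip(latency_rows, labels):
            for _ in range(n_trials_per):
                for neuron, lat in enumerate(latencies):
                    if np.isfinite(lat):
                        rows.append(
                            (trial, label, neuron,
                             lat + jitter * rng.normal())
                        )
                trial += 1
        return pd.DataFrame(
            rows, columns=["trial", "stimulus", "neuron", "time_ms"]
        )

    def test_disjoint_latency_orders_decoded_perfectly(self):
        events = self._events(
            [[12.0, 20.0, 30.0], [30.0, 20.0, 12.0]], ["a", "b"]
        )
        result = rank_order_decode(events, n_train=2, seed=0)
        assert result.accuracy == 100.0

    def test_hand_computed_rank_correlation(self):
        # class a ranks (1,2,3), class b ranks (3,2,1); a test trial with
        # latencies [12,20,30] correlates +1 with a's template and -1 with
        # b's, so it must be classified as a
        events = self._events(
            [[12.0, 20.0, 30.0], [30.0, 20.0, 12.0]], ["a", "b"]
        )
        from popfactor.decoding import first_spike_latencies, _rank_vector

        lat, labels = first_spike_latencies(events)
        ranks = np.apply_along_axis(_rank_vector, 1, lat)
        assert np.array_equal(ranks[0], [1, 2, 3])
        r = np.corrcoef(ranks[0], ranks[-1])[0, 1]
        assert r == pytest.approx(-1.0)
        result = rank_order_decode(events, n_train=2, seed=0)
        assert result.accuracy == 100.0

    def test_silent_neurons_share_max_rank(self):
        from popfactor.decoding import _rank_vector

        ranks = _rank_vector(np.array([10.0, np.inf, np.inf]))
        assert ranks[0] == 1.0
        assert ranks[1] == ranks[2] == 2.5

    def test_noisy_latencies_still_decoded(self):
        events = self._events(
            [[12.0, 20.0, 30.0, 45.0], [45.0, 30.0, 20.0, 12.0]],
            ["a", "b"], n_trials_per=8, jitter=3.0, seed=1,
        )
        result = rank_order_decode(events, n_train=4, seed=0)
        assert result.accuracy > 80.0
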