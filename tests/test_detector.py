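import numpy as np
import pandas as pd
import pytest

from ecgpeaks import (
    ECGRecord,
    SplitConfig,
    gini_index,
    rlc_correct,
    rlc_half_window,
    split_dataset,
    train_ensemble,
)
from ecgpeaks.detector import EnsembleMember, TrainedEnsemble
from sklearn.tree import DecisionTreeClassifier


class TestGini:
    @pytest.mark.parametrize(
        "probs, expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.9, 0.1], 0.18)],
    )
    def test_values(self, probs, expected):
        assert gini_index(probs) == pytest.approx(expected)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            gini_index([1.2, -0.2])

    def test_non_normalised_rejected(self):
        with pytest.raises(ValueError):
            gini_index([0.5, 0.4])


class TestSplitDataset:
    def test_single_stratum_80_20(self):
        res = split_dataset(["x"] * 100, SplitConfig(seed=1))
        assert res.train_idx.size == 80 and res.test_idx.size == 20
        assert len(res.folds) == 10
        assert set(res.train_idx) | set(res.test_idx) == set(range(100))

    def test_two_strata_split_independently(self):
        strata = ["a"] * 10 + ["b"] * 10
        res = split_dataset(strata, SplitConfig(seed=0))
        for s in "ab":
            members = {i for i in res.train_idx if strata[i] == s}
            assert len(members) == 8

    def test_deterministic_given_seed(self):
        strata = ["a"] * 30 + ["b"] * 20
        r1 = split_dataset(strata, SplitConfig(seed=5))
        r2 = split_dataset(strata, SplitConfig(seed=5))
        np.testing.assert_array_equal(r1.train_idx, r2.train_idx)
        np.testing.assert_array_equal(r1.test_idx, r2.test_idx)

    def test_tiny_stratum_goes_to_training(self, caplog):
        strata = ["a"] * 20 + ["rare"]
        res = split_dataset(strata, SplitConfig(seed=0))
        assert 20 in res.train_idx

    def test_folds_partition_training_set(self):
        res = split_dataset(["x"] * 50, SplitConfig(seed=2))
        all_val = np.sort(np.concatenate([v for _, v in res.folds]))
        np.testing.assert_array_equal(all_val, res.train_idx)


def separable_dataset(n=120, seed=0, n_noise=2):
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=n) > 0.5).astype(int)
    data = {"sep": y * 5.0 + rng.normal(scale=0.2, size=n)}
    for j in range(n_noise):
        data[f"noise{j}"] = rng.normal(size=n)
    return pd.DataFrame(data), y


class TestTrainEnsemble:
    def test_n4_trains_fifteen_trees(self):
        X, y = separable_dataset(n_noise=3)
        ens = train_ensemble(X, y, list(X.columns), SplitConfig(seed=0))
        assert len(ens.members) == 15  # 2^4 - 1

    def test_n3_with_large_ensemble_keeps_all_seven(self):
        X, y = separable_dataset(n_noise=2)
        ens = train_ensemble(X, y, list(X.columns), SplitConfig(seed=0, ensemble_size=16))
        assert len(ens.members) == 7

    def test_ensemble_size_truncates(self):
        X, y = separable_dataset(n_noise=3)
        ens = train_ensemble(X, y, list(X.columns), SplitConfig(seed=0, ensemble_size=5))
        assert len(ens.members) == 5
        accs = [m.val_accuracy for m in ens.members]
        assert accs == sorted(accs, reverse=True)

    def test_subsets_containing_separator_reach_full_cv_accuracy(self):
        X, y = separable_dataset()
        ens = train_ensemble(X, y, list(X.columns), SplitConfig(seed=0))
        for m in ens.members:
            if "sep" in m.features:
                assert m.val_accuracy == pytest.approx(1.0)

    def test_too_many_features_rejected(self):
        X, y = separable_dataset()
        with pytest.raises(ValueError):
            train_ensemble(X, y, [f"f{i}" for i in range(17)], SplitConfig())

    def test_retraining_same_seed_reproduces_votes(self):
        X, y = separable_dataset(n_noise=2)
        a = train_ensemble(X, y, list(X.columns), SplitConfig(seed=3))
        b = train_ensemble(X, y, list(X.columns), SplitConfig(seed=3))
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert [m.features for m in a.members] == [m.features for m in b.members]


def constant_tree(value):
    clf = DecisionTreeClassifier()
    clf.fit([[0.0], [1.0]], [value, value])
    return clf


def voting_ensemble(votes):
    members = [EnsembleMember(tree=constant_tree(v), features=("f",), val_accuracy=1.0) for v in votes]
    return TrainedEnsemble(members=members, feature_names=["f"])


class TestMajorityVote:
    X = pd.DataFrame({"f": [0.0]})

    def test_strict_majority_is_r(self):
        ens = voting_ensemble([1] * 9 + [0] * 7)
        assert ens.predict(self.X)[0] == 1

    def test_even_tie_resolves_to_r(self):
        ens = voting_ensemble([1] * 8 + [0] * 8)
        assert ens.predict(self.X)[0] == 1

    def test_no_votes_is_false_r(self):
        ens = voting_ensemble([0] * 16)
        assert ens.predict(self.X)[0] == 0

    def test_single_tree_reduces_to_that_tree(self):
        ens = voting_ensemble([1])
        assert ens.predict(self.X)[0] == 1
        assert voting_ensemble([0]).predict(self.X)[0] == 0

    def test_vote_fractions(self):
        ens = voting_ensemble([1] * 4 + [0] * 12)
        assert ens.vote_fractions(self.X)[0] == pytest.approx(0.25)


class TestRLC:
    @staticmethod
    def record(samples, fs=360.0):
        return ECGRecord(np.asarray(samples, dtype=float), fs=fs)

    def test_moves_to_neighbourhood_max(self):
        sig = np.zeros(20)
        sig[13] = 5.0  # k=10, max at k+3
        assert rlc_correct(self.record(sig), 10) == 13

    def test_max_at_k_unchanged(self):
        sig = np.zeros(20)
        sig[10] = 5.0
        assert rlc_correct(self.record(sig), 10) == 10

    def test_clipped_near_record_start(self):
        sig = np.zeros(20)
        sig[0] = 5.0
        assert rlc_correct(self.record(sig), 1) == 0

    def test_never_moves_more_than_half_window(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=2000)
        rec = self.record(sig)
        h = rlc_half_window(360.0)
        for k in rng.integers(0, 2000, size=50):
            c = rlc_correct(rec, int(k))
            assert abs(c - int(k)) <= h
            assert sig[c] >= sig[int(k)]

    def test_tie_breaks_to_earliest(self):
        sig = np.zeros(20)
        sig[8] = sig[12] = 5.0
        assert rlc_correct(self.record(sig), 10) == 8

    def test_half_window_scales_with_fs(self):
        assert rlc_half_window(360.0) == 4
        assert rlc_half_window(720.0) == 8
        assert rlc_half_window(100.0) == 1

    def test_absolute_mode_for_inverted_leads(self):
        sig = np.zeros(21)
        sig[13] = -5.0  # inverted QRS
        assert rlc_correct(self.record(sig), 10, absolute=True) == 13
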