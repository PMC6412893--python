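"""Stratified fold plans, boosting-across-folds bookkeeping, majority vote."""

import itertools

import numpy as np
import pytest

from sdaehar import boost_kfold as bk


class PerfectStub:
    """Reads the true class code out of column 0 of the feature matrix."""

    def predict(self, X):
        return X[:, 0].astype(int)


class ErrStub:
    """Misclassifies the first ``m`` rows of any matrix it predicts."""

    def __init__(self, m, n_classes=3):
        self.m, self.n_classes = m, n_classes

    def predict(self, X):
        y = X[:, 0].astype(int)
        out = y.copy()
        out[: self.m] = (y[: self.m] + 1) % self.n_classes
        return out


def coded_data(per_class=10, n_classes=3):
    """Features whose first column encodes the class."""
    y = np.repeat(np.arange(n_classes), per_class)
    X = np.column_stack([y.astype(float), np.linspace(0, 1, len(y))])
    return X, y


class TestStratifiedFolds:
    def test_balanced_validation_composition(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        plan = bk.stratified_folds(labels, k=5, seed=0)
        for _, va in plan.folds:
            assert (labels[va] == "a").sum() == 2
            assert (labels[va] == "b").sum() == 2

    def test_validation_sets_cover_everything(self):
        labels = np.repeat(np.arange(4), 8)
        plan = bk.stratified_folds(labels, k=4, seed=1)
        covered = np.sort(np.concatenate([va for _, va in plan.folds]))
        np.testing.assert_array_equal(covered, np.arange(32))

    def test_deterministic_under_seed(self):
        labels = np.repeat([0, 1], 20)
        p1 = bk.stratified_folds(labels, k=5, seed=9)
        p2 = bk.stratified_folds(labels, k=5, seed=9)
        for (t1, v1), (t2, v2) in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(v1, v2)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="k=5"):
            bk.stratified_folds(np.array([0] * 10 + [1] * 3), k=5)


class TestBackend:
    def test_separable_blobs_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(5, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        model = bk.fit_gbdt_backend(X, y, bk.GBDTParams(seed=0))
        assert (bk._quiet_predict(model, X) == y).mean() == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bk.fit_gbdt_backend(np.zeros((5, 2)), np.zeros(5))

    def test_fixed_seed_reproducible(self, rng):
        X = rng.random((60, 4))
        y = rng.integers(0, 3, 60)
        p1 = bk._quiet_predict(bk.fit_gbdt_backend(X, y, bk.GBDTParams(seed=4)), X)
        p2 = bk._quiet_predict(bk.fit_gbdt_backend(X, y, bk.GBDTParams(seed=4)), X)
        np.testing.assert_array_equal(p1, p2)

    def test_xgboost_backend_available(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        model = bk.fit_gbdt_backend(X, y, bk.GBDTParams(backend="xgboost", seed=0))
        assert (bk._quiet_predict(model, X) == y).mean() == 1.0


class TestBoostingKFold:
    def test_perfect_backend_reduces_to_plain_kfold(self):
        X, y = coded_data()
        plan = bk.stratified_folds(y, k=5, seed=0)
        seen = []
        model = bk.train_boosting_kfold(
            X, y, plan, fit_fn=lambda Xt, yt: seen.append((Xt, yt)) or PerfectStub()
        )
        assert model.misjudged_counts == [0] * 5
        for (Xt, yt), (tr_idx, _) in zip(seen, plan.folds):
            np.testing.assert_array_equal(Xt, X[tr_idx])
            np.testing.assert_array_equal(yt, y[tr_idx])

    def test_fold2_grows_by_exactly_m(self):
        X, y = coded_data()
        plan = bk.stratified_folds(y, k=5, seed=0)
        m = 4
        fits = []

        def fit_fn(Xt, yt):
            fits.append(len(yt))
            return ErrStub(m) if len(fits) == 1 else PerfectStub()

        model = bk.train_boosting_kfold(X, y, plan, fit_fn=fit_fn)
        base = [len(tr) for tr, _ in plan.folds]
        assert model.misjudged_counts[0] == m
        assert model.train_sizes[0] == base[0]
        assert model.train_sizes[1] == base[1] + m

    def test_misjudged_set_replaced_not_accumulated(self):
        X, y = coded_data()
        plan = bk.stratified_folds(y, k=5, seed=0)
        fits = []

        def fit_fn(Xt, yt):
            fits.append(len(yt))
            # fold 1 makes 4 errors, fold 2 makes 2, later folds none
            return [ErrStub(4), ErrStub(2)][len(fits) - 1] if len(fits) <= 2 else PerfectStub()

        model = bk.train_boosting_kfold(X, y, plan, fit_fn=fit_fn)
        base = [len(tr) for tr, _ in plan.folds]
        assert model.misjudged_counts[:2] == [4, 2]
        assert model.train_sizes[2] == base[2] + 2  # not + 6

    def test_duplicated_rows_are_the_misjudged_samples(self):
        X, y = coded_data()
        plan = bk.stratified_folds(y, k=3, seed=1)
        captured = []

        def fit_fn(Xt, yt):
            captured.append(Xt)
            return ErrStub(3) if len(captured) == 1 else PerfectStub()

        bk.train_boosting_kfold(X, y, plan, fit_fn=fit_fn)
        val1 = X[plan.folds[0][1]]
        np.testing.assert_array_equal(captured[1][-3:], val1[:3])

    def test_k1_plan_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            bk.FoldPlan(k=1, folds=[(np.arange(5), np.arange(5, 10))])


class TestMajorityVote:
    def _model(self, vote_lists):
        class Fixed:
            def __init__(self, v):
                self.v = np.asarray(v)

            def predict(self, X):
                return self.v

        return bk.BoostKFoldModel(
            models=[Fixed(v) for v in vote_lists],
            classes=np.arange(3),
            misjudged_counts=[0] * len(vote_lists),
            train_sizes=[0] * len(vote_lists),
        )

    def test_unanimous(self):
        model = self._model([[2]] * 5)
        assert bk.predict_majority_vote(model, np.zeros((1, 1)))[0] == 2

    def test_tie_breaks_to_smaller_class(self):
        # votes 2,2,1,1,0 -> counts {0:1, 1:2, 2:2}; tie 1 vs 2 -> 1
        model = self._model([[2], [2], [1], [1], [0]])
        assert bk.predict_majority_vote(model, np.zeros((1, 1)))[0] == 1

    def test_strict_majority(self):
        model = self._model([[0], [0], [0], [1], [2]])
        assert bk.predict_majority_vote(model, np.zeros((1, 1)))[0] == 0

    def test_exhaustive_against_bincount_oracle(self):
        # all 3-class patterns of 5 votes
        for votes in itertools.product(range(3), repeat=5):
            model = self._model([[v] for v in votes])
            got = bk.predict_majority_vote(model, np.zeros((1, 1)))[0]
            expected = np.argmax(np.bincount(np.array(votes)))
            assert got == expected, votes

    def test_decodes_original_labels(self):
        X, y = coded_data()
        y_named = np.array(["walk", "sit", "lay"])[y]
        plan = bk.stratified_folds(y_named, k=3, seed=0)
        model = bk.train_boosting_kfold(X, y_named, plan, fit_fn=lambda *_: PerfectStub())
        pred = bk.predict_majority_vote(model, X)
        np.testing.assert_array_equal(pred, y_named)
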