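import itertools

import numpy as np
import pandas as pd
import pytest

from ubisite.bayes import (
    EBMC,
    TARGET,
    FeatureSelectionNB,
    ModelAveragedNB,
    NaiveBayes,
    NaiveBayesResults,
    chain_child_cpts,
)
from ubisite.scoring import count_table, fit_cpt, k2_log_score


def disc_frame(arr, cols=None):
    arr = np.asarray(arr, dtype=int)
    return pd.DataFrame(arr, columns=cols or [f"f{i}" for i in range(arr.shape[1])])


class TestNaiveBayes:
    def test_prior_with_laplace_on_balanced_data(self):
        X = disc_frame([[0], [1], [2], [0]])
        res = NaiveBayes(X, [0, 0, 1, 1]).fit()
        np.testing.assert_allclose(res.class_prior, [0.5, 0.5])

    def test_feature_tracking_the_label_gets_near_diagonal_cpt(self):
        y = np.tile([0, 1], 30)
        X = disc_frame(y.reshape(-1, 1))
        res = NaiveBayes(X, y).fit()
        cpt = np.exp(res.log_cpts[0])  # (2 classes, 3 bins)
        assert cpt[0, 0] > 0.9 and cpt[1, 1] > 0.9

    def test_zero_features_reduces_to_prior(self):
        X = pd.DataFrame(index=range(6))
        res = NaiveBayes(X, [0, 0, 0, 1, 1, 1]).fit()
        proba = res.predict_proba(pd.DataFrame(index=range(2)))
        np.testing.assert_allclose(proba, [[0.5, 0.5], [0.5, 0.5]])

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            NaiveBayes(disc_frame([[0], [1]]), [1, 1])

    def test_hand_computed_two_feature_posterior(self):
        # prior (.5,.5); P(x1|1)=.8, P(x1|0)=.2; P(x2|1)=.6, P(x2|0)=.4
        # P(T=1 | x) = .5*.8*.6 / (.5*.8*.6 + .5*.2*.4) = 6/7
        model = NaiveBayes(disc_frame([[1, 1], [0, 0]], ["a", "b"]), [1, 0], n_bins=2)
        log_cpts = np.log([
            [[0.8, 0.2], [0.2, 0.8]],  # feature a: rows T=0, T=1
            [[0.6, 0.4], [0.4, 0.6]],  # feature b
        ])
        res = NaiveBayesResults(model=model, class_prior=np.array([0.5, 0.5]),
                                features=["a", "b"], log_cpts=log_cpts)
        proba = res.predict_proba(disc_frame([[1, 1]], ["a", "b"]))
        assert proba[0, 1] == pytest.approx(6 / 7, abs=1e-12)

    def test_posterior_normalized_and_order_invariant(self, small_disc):
        X, y = small_disc
        res = NaiveBayes(X, y).fit()
        proba = res.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        res_perm = NaiveBayes(X[["c", "a", "b"]], y).fit()
        np.testing.assert_allclose(
            proba, res_perm.predict_proba(X[["c", "a", "b"]]), atol=1e-12
        )

    def test_value_beyond_declared_arity_rejected_at_predict(self, small_disc):
        X, y = small_disc
        res = NaiveBayes(X, y).fit()
        bad = X.copy()
        bad.iloc[0, 0] = 7
        with pytest.raises(ValueError, match="arity"):
            res.predict_proba(bad)


class TestFeatureSelectionNB:
    def test_pure_noise_selects_nothing_and_predicts_prior(self):
        rng = np.random.default_rng(0)
        X = disc_frame(rng.integers(0, 3, size=(400, 6)))
        y = np.tile([0, 1], 200)
        res = FeatureSelectionNB(X, y).fit()
        assert res.selection_order == []
        np.testing.assert_allclose(res.predict_proba(X)[:, 1], 0.5, atol=1e-12)

    def test_planted_feature_found_first_matching_score_oracle(self):
        rng = np.random.default_rng(42)
        n = 200
        y = rng.integers(0, 2, n)
        X = disc_frame(rng.integers(0, 3, size=(n, 21)))
        planted = np.where(rng.random(n) < 0.1, 1 - y, y)
        X["f7"] = planted
        model = FeatureSelectionNB(X, y)
        res = model.fit()
        assert res.selection_order[0] == "f7"
        # exhaustive single-feature oracle: K2 gain of adding each feature alone
        data = X.copy()
        data[TARGET] = y
        gains = {
            f: k2_log_score(data, f, [TARGET], model.arities)
            - k2_log_score(data, f, [], model.arities)
            for f in X.columns
        }
        assert max(gains, key=gains.get) == "f7"

    def test_score_trace_strictly_increasing(self, signal_dataset):
        disc = signal_dataset["discretized"]
        res = FeatureSelectionNB.from_matrix(disc).fit()
        trace = np.asarray(res.score_trace)
        assert len(trace) >= 2
        assert (np.diff(trace) > 0).all()
        assert set(res.selection_order) <= set(disc.X.columns)


class TestModelAveragedNB:
    def test_arc_weight_saturates_for_label_copy(self):
        y = np.tile([0, 1], 20)
        X = disc_frame(y.reshape(-1, 1))
        res = ModelAveragedNB(X, y).fit()
        assert res.arc_weights[0] > 0.99

    def test_arc_weight_below_half_for_independent_feature(self):
        rng = np.random.default_rng(14)
        X = disc_frame(rng.integers(0, 3, size=(500, 1)))
        y = rng.integers(0, 2, 500)
        res = ModelAveragedNB(X, y).fit()
        assert res.arc_weights[0] < 0.5

    def test_arc_prior_near_one_forces_all_weights_to_one(self, small_disc):
        X, y = small_disc
        res = ModelAveragedNB(X, y, arc_prior=1 - 1e-12).fit()
        np.testing.assert_allclose(res.arc_weights, 1.0, atol=1e-6)

    def test_weight_one_reduces_to_naive_bayes(self, small_disc):
        X, y = small_disc
        res = ModelAveragedNB(X, y).fit()
        res.arc_weights = np.ones_like(res.arc_weights)
        nb = NaiveBayes(X, y).fit()
        np.testing.assert_allclose(
            res.predict_proba(X), nb.predict_proba(X), atol=1e-12
        )

    def test_weight_zero_reduces_to_prior(self, small_disc):
        X, y = small_disc
        res = ModelAveragedNB(X, y).fit()
        res.arc_weights = np.zeros_like(res.arc_weights)
        prior = res.class_prior
        np.testing.assert_allclose(res.predict_proba(X), np.tile(prior, (len(X), 1)),
                                   atol=1e-12)

    def test_equals_brute_force_subset_enumeration(self, small_disc):
        """Central oracle: the O(n) arc-weight form equals explicit averaging
        of all 2^n subset-model joints weighted by prior x marginal likelihood."""
        X, y = small_disc
        model = ModelAveragedNB(X, y, arc_prior=0.5)
        res = model.fit()
        data = X.copy()
        data[TARGET] = y
        F = len(model.features)
        m1 = np.array([k2_log_score(data, f, [TARGET], model.arities)
                       for f in model.features])
        m0 = np.array([k2_log_score(data, f, [], model.arities)
                       for f in model.features])
        cond = res.cond_cpts
        marg = res.marg_cpts
        shift = max(m1.sum(), m0.sum())
        rows = X.to_numpy()[:12]
        brute = []
        for x in rows:
            num = np.zeros(2)
            for S in itertools.product([0, 1], repeat=F):
                logw = sum(
                    (np.log(0.5) + m1[i]) if S[i] else (np.log(0.5) + m0[i])
                    for i in range(F)
                )
                for t in (0, 1):
                    lik = res.class_prior[t]
                    for i in range(F):
                        lik *= cond[i, t, x[i]] if S[i] else marg[i, x[i]]
                    num[t] += np.exp(logw - shift) * lik
            brute.append(num / num.sum())
        fast = res.predict_proba(pd.DataFrame(rows, columns=model.features))
        np.testing.assert_allclose(np.asarray(brute), fast, atol=1e-9)

    def test_invalid_arc_prior_rejected(self, small_disc):
        X, y = small_disc
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError, match="arc_prior"):
                ModelAveragedNB(X, y, arc_prior=bad)


class TestEBMC:
    def test_null_data_yields_empty_model_and_prior_posterior(self):
        rng = np.random.default_rng(1)
        X = disc_frame(rng.integers(0, 3, size=(300, 8)))
        y = rng.integers(0, 2, 300)
        res = EBMC(X, y).fit()
        assert res.children == [] and res.parents == []
        proba = res.predict_proba(X)
        np.testing.assert_allclose(proba, np.tile(res.class_prior, (300, 1)),
                                   atol=1e-12)

    def test_strong_feature_enters_model_matching_one_step_oracle(self, small_disc):
        X, y = small_disc
        model = EBMC(X, y)
        res = model.fit()
        included = set(res.children) | set(res.parents)
        assert "a" in included
        from ubisite.scoring import target_family_score

        data = X.copy()
        data[TARGET] = y
        scores = {
            f: target_family_score(data, TARGET, [f], model.arities)
            for f in X.columns
        }
        assert max(scores, key=scores.get) == "a" == res.children[0]

    def test_conversion_preserves_training_posteriors(self):
        """Parents-of-target model vs its children-of-target (chain) conversion:
        identical training posteriors under maximum-likelihood CPTs."""
        rng = np.random.default_rng(1)
        n = 400
        X = disc_frame(rng.integers(0, 3, size=(n, 2)), ["a", "b"])
        y = ((X["a"] + X["b"] + rng.integers(0, 2, n)) % 2).to_numpy()
        data = X.copy()
        data[TARGET] = y
        arit = {"a": 3, "b": 3, TARGET: 2}
        pre = fit_cpt(count_table(data, TARGET, ["a", "b"], arit), 0.0).lookup(
            X.to_numpy()
        )
        cpts = chain_child_cpts(data, TARGET, ["a", "b"], arit, 0.0)
        prior = fit_cpt(count_table(data, TARGET, [], arit), 0.0).table[0]
        logp = np.tile(np.log(prior), (n, 1))
        for j, c in enumerate(["a", "b"]):
            cvals = data[c].to_numpy()
            ev = data[["a", "b"][:j]].to_numpy()
            for t in (0, 1):
                pv = np.column_stack([np.full(n, t, dtype=int), ev])
                rows = cpts[j].lookup(pv)
                logp[:, t] += np.log(rows[np.arange(n), cvals])
        post = np.exp(logp)
        post /= post.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(post, pre, atol=1e-9)

    def test_parent_phase_engages_when_children_capped(self, small_disc):
        X, y = small_disc
        rng = np.random.default_rng(9)
        X = X.copy()
        # second informative feature so phase B has something to add
        X["d"] = np.where(rng.random(len(y)) < 0.8, y, rng.integers(0, 3, len(y)))
        res = EBMC(X, y, max_children=1).fit()
        assert len(res.children) == 1
        assert len(res.parents) >= 1
        assert set(res.children).isdisjoint(res.parents)

    def test_posterior_equals_joint_enumeration_oracle(self, small_disc):
        X, y = small_disc
        rng = np.random.default_rng(9)
        X = X.copy()
        X["d"] = np.where(rng.random(len(y)) < 0.8, y, rng.integers(0, 3, len(y)))
        res = EBMC(X, y, max_children=1).fit()
        rows = X.iloc[:10]
        fast = res.predict_proba(rows)
        # scalar-by-scalar factor lookup, independent of the vectorized path
        for i in range(len(rows)):
            num = np.zeros(2)
            for t in (0, 1):
                if res.parents:
                    pv = np.array([[rows.iloc[i][p] for p in res.parents]])
                    f = res.target_cpt.lookup(pv)[0, t]
                else:
                    f = res.class_prior[t]
                for j, c in enumerate(res.children):
                    conf = [t] + [int(rows.iloc[i][e]) for e in res.children[:j]]
                    pv = np.array([conf])
                    f *= res.child_cpts[j].lookup(pv)[0, int(rows.iloc[i][c])]
                num[t] = f
            np.testing.assert_allclose(fast[i], num / num.sum(), atol=1e-12)

    def test_score_traces_strictly_increasing(self, signal_dataset):
        res = EBMC.from_matrix(signal_dataset["discretized"]).fit()
        assert res.children  # the planted signal must pull something in
        for trace in res.score_trace:
            assert (np.diff(np.asarray(trace)) > 0).all()


def test_all_posteriors_sum_to_one_on_real_fixture(signal_dataset):
    disc = signal_dataset["discretized"]
    for cls in (NaiveBayes, FeatureSelectionNB, ModelAveragedNB, EBMC):
        res = cls.from_matrix(disc).fit()
        proba = res.predict_proba(disc.X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert res.summary()  # summaries render without error
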