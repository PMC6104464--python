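import numpy as np
import pytest

from conftest import toy_cohort
from petrad.model import (
    ModelSpec,
    NodalModel,
    loo_gmean,
    make_split,
    reduce_features,
    select_model,
    spearman,
    train_final_ensemble,
)
from petrad.nn import n_parameters, train_network_raw
from petrad.screen import UnivariateResult


def blobs_cohort(rng, n=60, n_pos=15, sep=4.0, extra_noise_features=0):
    """Two well-separated Gaussian blobs in 2 features."""
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    feats = {
        "f1": rng.normal(0, 1, n) + sep * y,
        "f2": rng.normal(0, 1, n) + sep * y,
    }
    for k in range(extra_noise_features):
        feats[f"noise{k}"] = rng.normal(size=n)
    return toy_cohort(feats, y)


class TestSpearman:
    def test_monotone_transform(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman(x, x**2) == pytest.approx(1.0)

    def test_reversed(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert spearman([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0


class TestReduceFeatures:
    def _cohort_with_correlations(self, rng):
        n = 40
        y = np.array([1] * 10 + [0] * 30)
        f1 = rng.normal(size=n) + y
        f2 = f1 + rng.normal(0, 0.1, n)  # |rho| vs f1 ~ 0.99
        f3 = rng.normal(size=n) + 0.5 * y  # independent of f1
        return toy_cohort({"f1": f1, "f2": f2, "f3": f3}, y)

    def _results(self, ps):
        return [
            UnivariateResult(name, p, 0.8, "positive-high", 0.0)
            for name, p in ps.items()
        ]

    def test_greedy_rule_drops_redundant(self, rng):
        cohort = self._cohort_with_correlations(rng)
        selected = reduce_features(
            self._results({"f1": 1e-4, "f2": 1e-3, "f3": 5e-3}), cohort
        )
        assert selected == ["f1", "f3"]

    def test_disabled_gate_keeps_all(self, rng):
        from petrad.model import ReductionConfig

        cohort = self._cohort_with_correlations(rng)
        selected = reduce_features(
            self._results({"f1": 1e-4, "f2": 1e-3, "f3": 5e-3}),
            cohort,
            ReductionConfig(rho_threshold=1.0),
        )
        assert selected == ["f1", "f2", "f3"]

    def test_no_feature_passes(self, rng):
        cohort = self._cohort_with_correlations(rng)
        with pytest.warns(UserWarning, match="no feature"):
            assert reduce_features(self._results({"f1": 0.5}), cohort) == []


class TestMakeSplit:
    def test_reference_rounding(self):
        y = np.array([1] * 20 + [0] * 65)  # 85 patients, 20 positive
        tr, va = make_split(y, 72, 13, seed=0)
        assert len(tr) == 72 and len(va) == 13
        assert y[va].sum() == 3  # round(13 * 20/85) = 3
        assert y[tr].sum() == 17

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            make_split(np.zeros(20, dtype=int), 15, 5, seed=0)

    def test_determinism_and_variation(self):
        y = np.array([1] * 10 + [0] * 30)
        a1 = make_split(y, 34, 6, seed=5)
        a2 = make_split(y, 34, 6, seed=5)
        np.testing.assert_array_equal(a1[0], a2[0])
        distinct = {tuple(make_split(y, 34, 6, seed=s)[1]) for s in range(50)}
        assert len(distinct) > 40


class TestTrainNetwork:
    def test_parameter_count_formula(self):
        assert ModelSpec(("a", "b"), 3).n_parameters == 13
        for n_in in (1, 2, 4):
            for h in (2, 3, 5):
                rng = np.random.default_rng(0)
                X = rng.normal(size=(30, n_in))
                y = (rng.random(30) > 0.5).astype(int)
                y[:2] = [0, 1]
                net = train_network_raw(X, y, X[:5], y[:5], n_hidden=h, max_epochs=2)
                assert net.n_parameters == n_parameters(n_in, h)

    def test_separable_blobs_high_accuracy(self, rng):
        n = 85
        y = np.array([1] * 20 + [0] * 65)
        X = np.column_stack([rng.normal(0, 1, n) + 6 * y, rng.normal(0, 1, n) + 6 * y])
        net = train_network_raw(X, y, X[:20], y[:20], n_hidden=3, seed=0)
        acc = ((net.predict(X) >= 0.5).astype(int) == y).mean()
        assert acc >= 0.95

    def test_outputs_in_unit_interval_and_normalization(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        net = train_network_raw(X, y, X[:8], y[:8], n_hidden=2, seed=1)
        out = net.predict(rng.normal(size=(100, 2)) * 10)
        assert ((out > 0) & (out < 1)).all()
        z = net.normalize(np.vstack([net.x_min, net.x_max]))
        np.testing.assert_allclose(z, [[-1, -1], [1, 1]])

    def test_constant_input_rejected(self, rng):
        X = np.column_stack([np.full(20, 2.0), rng.normal(size=20)])
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="column"):
            train_network_raw(X, y, X[:4], y[:4], n_hidden=2)

    def test_positive_weight_raises_sensitivity(self, rng):
        # imbalanced overlapping toy: quadrupling the positive-case loss
        # weight should not lower sensitivity (median over seeds)
        sens = {1.0: [], 4.0: []}
        n = 80
        y = np.array([1] * 8 + [0] * 72)
        for seed in range(11):
            r = np.random.default_rng(seed)
            X = np.column_stack(
                [r.normal(0, 1, n) + 1.5 * y, r.normal(0, 1, n) + 1.5 * y]
            )
            for w in (1.0, 4.0):
                net = train_network_raw(
                    X, y, X, y, n_hidden=3, positive_weight=w, seed=seed
                )
                pred = (net.predict(X) >= 0.5).astype(int)
                sens[w].append(pred[y == 1].mean())
        assert np.median(sens[4.0]) >= np.median(sens[1.0])


class TestLOOGmean:
    def test_separable_cohort(self, rng):
        cohort = blobs_cohort(rng, n=30, n_pos=8)
        spec = ModelSpec(("f1", "f2"), 2)
        res = loo_gmean(cohort, spec, n_sessions=2, seed=0)
        assert res.mean_gmean >= 0.9

    def test_gmean_arithmetic(self):
        from petrad.framework import gmean

        assert gmean(0.75, 0.81) == pytest.approx(0.7794, abs=1e-4)


class TestEnsemble:
    def test_prediction_is_member_mean_and_order_invariant(self, rng):
        cohort = blobs_cohort(rng, n=24, n_pos=6)
        spec = ModelSpec(("f1", "f2"), 2)
        ens = train_final_ensemble(cohort, spec, n_runs=4, seed=0)
        X = cohort.feature_frame()[["f1", "f2"]].to_numpy()
        manual = np.mean([m.predict(X) for m in ens.members], axis=0)
        np.testing.assert_allclose(ens.predict(X), manual)
        ens.members.reverse()
        np.testing.assert_allclose(ens.predict(X), manual)

    def test_classification_threshold(self, rng):
        cohort = blobs_cohort(rng, n=24, n_pos=6)
        ens = train_final_ensemble(cohort, ModelSpec(("f1", "f2"), 2), n_runs=3, seed=1)
        frame = cohort.feature_frame()
        pred = ens.classify(frame)
        out = ens.predict(frame)
        np.testing.assert_array_equal(pred, (out >= 0.5).astype(int))


class TestSelectModel:
    def test_single_candidate_returned(self, rng):
        cohort = blobs_cohort(rng, n=24, n_pos=6)
        spec = select_model(
            cohort, ["f1"], hidden_options=(2, 3), n_sessions=1, seed=0
        )
        assert spec.input_features == ("f1",)
        assert spec.hidden_neurons in (2, 3)

    def test_informative_pair_recovered(self, rng):
        cohort = blobs_cohort(rng, n=30, n_pos=8, extra_noise_features=1)
        spec = select_model(
            cohort, ["f1", "f2", "noise0"], hidden_options=(2,), n_sessions=1, seed=0
        )
        assert set(spec.input_features) & {"f1", "f2"}


class TestNodalModelFacade:
    def test_fit_evaluate_summary(self, rng):
        cohort = blobs_cohort(rng, n=30, n_pos=8)
        results = NodalModel(cohort, ["f1", "f2"], hidden_neurons=3).fit(
            n_runs=5, seed=0
        )
        rep = results.evaluate(cohort)
        assert rep.sensitivity >= 0.8 and rep.specificity >= 0.8
        assert "13 parameters" in results.summary()
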