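"""Integrated gradients and its post-processing: exactness on linear models,
completeness, log-modulus, scaling, top-feature selection."""

import numpy as np
import pytest

from snvorigin.attribution import (AttributionMatrix, attribute_cohort,
                                   class_mean_attributions, display_order,
                                   integrated_gradients, log_modulus,
                                   log_modulus_matrix, scale_attributions,
                                   top_features)


class LinearScorer:
    """Two-class model with pre-softmax score F_1(x) = w . x, F_0 = 0.

    Serves as the closed-form oracle: IG of a linear scorer is exactly
    w_j * x_j for any number of interpolation steps.
    """

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def predict_proba(self, xs):
        s = xs[0] @ self.w
        logits = np.stack([np.zeros_like(s), s], axis=1)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def input_gradients(self, xs, class_idx, mode="logit"):
        n = xs[0].shape[0]
        g = np.tile(self.w if class_idx == 1 else np.zeros_like(self.w), (n, 1))
        return [g]


class TestIntegratedGradients:
    def test_zero_input_gives_zero_attributions(self, trained_tiny):
        model, data = trained_tiny
        xs = [np.zeros(X.shape[1]) for X in data.Xs_train]
        attr = integrated_gradients(model, xs, steps=20)
        assert all(np.allclose(a, 0.0) for a in attr)

    @pytest.mark.parametrize("steps", [1, 7, 50])
    def test_linear_scorer_recovered_exactly(self, steps):
        w = np.array([1.5, -2.0, 0.25, 0.0])
        x = np.array([2.0, 1.0, -4.0, 3.0])
        attr, = integrated_gradients(LinearScorer(w), [x], steps=steps, target=1)
        assert np.allclose(attr, w * x, atol=1e-12)

    def test_completeness_axiom_on_trained_model(self, trained_tiny):
        """sum_j IG_j approximates F_c(x) - F_c(0) within 1% at 300 steps,
        and the Riemann error shrinks as steps grow."""
        model, data = trained_tiny
        xs = [X[0] for X in data.Xs_test]
        xs_batched = [x.reshape(1, -1) for x in xs]
        c = int(model.predict_proba(xs_batched).argmax())
        f_x = model._forward(xs_batched)[0, c]
        f_0 = model._forward([np.zeros_like(x) for x in xs_batched])[0, c]
        gap = f_x - f_0
        errs = {}
        for steps in (50, 300, 3000):
            total = sum(a.sum() for a in
                        integrated_gradients(model, xs, steps=steps, target=c))
            errs[steps] = abs(total - gap) / max(abs(gap), 1e-12)
        assert errs[300] < 0.01
        assert errs[3000] <= errs[50] + 1e-9

    def test_attributions_follow_top_predicted_class(self, trained_tiny):
        model, data = trained_tiny
        xs = [X[1] for X in data.Xs_test]
        top = int(model.predict_proba([x.reshape(1, -1) for x in xs]).argmax())
        auto = integrated_gradients(model, xs, steps=25)
        explicit = integrated_gradients(model, xs, steps=25, target=top)
        assert all(np.array_equal(a, b) for a, b in zip(auto, explicit))

    def test_invalid_steps_rejected(self, trained_tiny):
        model, data = trained_tiny
        with pytest.raises(ValueError):
            integrated_gradients(model, [X[0] for X in data.Xs_test], steps=0)


class TestClassMeans:
    def test_single_sample_class_equals_its_attribution(self):
        attr = np.array([[1.0, -2.0], [3.0, 4.0]])
        mat = class_mean_attributions(attr, ["a", "b"], ["a", "b"], ["f1", "f2"])
        assert np.array_equal(mat.values, attr)
        assert mat.stage == "raw_mean"

    def test_opposite_attributions_cancel(self):
        attr = np.array([[1.0, -2.0], [-1.0, 2.0]])
        mat = class_mean_attributions(attr, ["a", "a"], ["a"], ["f1", "f2"])
        assert np.allclose(mat.values, 0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        attr = rng.normal(size=(6, 3))
        labels = ["a", "b", "a", "b", "a", "b"]
        perm = rng.permutation(6)
        m1 = class_mean_attributions(attr, labels, ["a", "b"], list("xyz"))
        m2 = class_mean_attributions(attr[perm], [labels[i] for i in perm],
                                     ["a", "b"], list("xyz"))
        assert np.allclose(m1.values, m2.values)

    def test_empty_class_warns_with_nan_row(self):
        with pytest.warns(UserWarning, match="no samples"):
            mat = class_mean_attributions(np.ones((1, 2)), ["a"], ["a", "b"],
                                          ["f1", "f2"])
        assert np.isnan(mat.values[1]).all()


class TestLogModulus:
    def test_fixed_points(self):
        assert log_modulus(np.array([0.0]))[0] == 0.0
        assert log_modulus(np.array([np.e - 1]))[0] == pytest.approx(1.0)
        assert log_modulus(np.array([-(np.e - 1)]))[0] == pytest.approx(-1.0)

    def test_odd_and_monotone(self):
        x = np.linspace(-10, 10, 201)
        y = log_modulus(x)
        assert np.allclose(y, -log_modulus(-x))
        assert np.all(np.diff(y) > 0)


class TestScaling:
    def matrix(self, values):
        values = np.asarray(values, dtype=float)
        return AttributionMatrix(values, [f"c{i}" for i in range(values.shape[0])],
                                 [f"f{j}" for j in range(values.shape[1])],
                                 stage="log_modulus")

    def test_extremes_map_to_plus_minus_one(self):
        out = scale_attributions(self.matrix([[2.0, -4.0, 0.0]]))
        assert out.values.tolist() == [[1.0, -1.0, 0.0]]

    def test_all_positive_matrix_tops_at_one(self):
        out = scale_attributions(self.matrix([[1.0, 2.0], [3.0, 4.0]]))
        assert out.values.max() == 1.0
        assert np.all(out.values > 0)

    def test_scale_invariance_under_doubling(self):
        m = self.matrix([[2.0, -3.0, 0.5], [-1.0, 4.0, 0.0]])
        a = scale_attributions(m)
        b = scale_attributions(self.matrix(m.values * 2))
        assert np.allclose(a.values, b.values)

    def test_literal_mode_flips_negatives(self):
        out = scale_attributions(self.matrix([[2.0, -4.0]]), literal=True)
        assert out.values.tolist() == [[1.0, 1.0]]

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning, match="no-op"):
            out = scale_attributions(self.matrix([[0.0, 0.0]]))
        assert np.all(out.values == 0)

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        out = scale_attributions(self.matrix(rng.normal(size=(5, 20))))
        assert out.values.min() >= -1.0 and out.values.max() <= 1.0


class TestTopFeatures:
    def test_union_cardinality_and_dedup(self):
        # 4 classes, 1 top bin each; class 0 and 1 share their top bin
        values = np.zeros((4, 6))
        values[0, 0] = 5.0
        values[1, 0] = 4.0
        values[2, 1] = -3.0
        values[3, 2] = 2.0
        mat = AttributionMatrix(values, list("abcd"), [f"b{j}" for j in range(6)])
        out = top_features(mat, {"bins": np.arange(6)}, {"bins": 1})
        assert out["bins"] == ["b0", "b1", "b2"]
        assert len(out["bins"]) <= 4

    def test_zero_attribution_features_excluded(self):
        values = np.zeros((2, 3))
        values[0, 1] = 1.0
        mat = AttributionMatrix(values, ["a", "b"], ["f0", "f1", "f2"])
        out = top_features(mat, {"tri": np.arange(3)}, {"tri": 2})
        assert "f0" not in out["tri"] and "f2" not in out["tri"]

    def test_oversized_k_capped_with_warning(self):
        mat = AttributionMatrix(np.ones((2, 2)), ["a", "b"], ["f0", "f1"])
        with pytest.warns(UserWarning, match="capped"):
            out = top_features(mat, {"drivers": np.arange(2)}, {"drivers": 10})
        assert out["drivers"] == ["f0", "f1"]

    def test_requires_raw_mean_stage(self):
        mat = AttributionMatrix(np.ones((1, 2)), ["a"], ["f0", "f1"], stage="scaled")
        with pytest.raises(ValueError):
            top_features(mat, {"bins": np.arange(2)})

    def test_enriched_bin_ranks_high_in_its_class(self, trained_tiny, tiny_cohort):
        """The generator concentrates each class's mutations in a few bins;
        those bins should surface among the class's top bin attributions."""
        model, data = trained_tiny
        attr = attribute_cohort(model, data.Xs_test, steps=50)
        feat_names = [n for fs in ("bins", "tri", "drivers")
                      for n in data.feature_names[fs]]
        mat = class_mean_attributions(attr, data.test_labels, data.class_names,
                                      feat_names)
        n_bins = len(tiny_cohort.bins)
        hits = 0
        for i, cls in enumerate(data.class_names):
            c = tiny_cohort.truth.class_names.index(cls)
            top_profile_bin = int(np.argmax(tiny_cohort.truth.bin_profiles[c]))
            rank = np.argsort(-np.abs(mat.values[i, :n_bins]), kind="stable")
            hits += top_profile_bin in rank[:3]
        assert hits >= len(data.class_names) // 2


def test_display_order_reuses_reference_ranking():
    ref = AttributionMatrix(np.array([[3.0, 1.0, 2.0]]), ["a"], list("xyz"))
    order = display_order(ref)
    assert order["a"] == [0, 2, 1]
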