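"""Min-max scaling, OVA linear SVMs, Eq.-style max-of-squared-weights RFE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import hrvselect as hv
from hrvselect.ranking import BinarySVMModel


class TestMinMaxNormalize:
    def test_affine_map(self):
        Xn, rec = hv.minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(Xn.ravel(), [0.0, 0.5, 1.0])
        assert rec.mins[0] == 2.0 and rec.maxs[0] == 6.0

    def test_idempotent_on_unit_range(self):
        X = np.array([[0.0], [0.25], [1.0]])
        Xn, _ = hv.minmax_normalize(X)
        assert np.allclose(Xn, X)

    def test_constant_column_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            Xn, _ = hv.minmax_normalize(np.array([[5.0], [5.0], [5.0]]))
        assert np.allclose(Xn, 0.0)

    def test_record_reapplies_to_held_out_rows(self):
        X = np.array([[0.0, 10.0], [2.0, 30.0], [4.0, 20.0]])
        _, rec = hv.minmax_normalize(X)
        held = rec.transform(np.array([[1.0, 25.0]]))
        assert np.allclose(held, [[0.25, 0.75]])


class TestOVASVMs:
    def test_three_classes_give_three_models(self, separable_toy):
        X, y = separable_toy
        models = hv.train_ova_svms(X, y, C=1.0)
        assert [m.positive_class for m in models] == ["control", "SS", "LS"]

    def test_separable_training_accuracy_is_one(self, separable_toy):
        X, y = separable_toy
        models = hv.train_ova_svms(X, y)
        pred = [hv.ova_predict(models, x) for x in X]
        assert np.mean(np.array(pred) == y) == 1.0

    def test_1d_positive_class_at_larger_values_has_positive_weight(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1], [2.0], [2.1]])
        y = np.array(["control", "control", "SS", "SS", "LS", "LS"])
        models = hv.train_ova_svms(X, y)
        ls = next(m for m in models if m.positive_class == "LS")
        control = next(m for m in models if m.positive_class == "control")
        assert ls.w[0] > 0
        assert control.w[0] < 0

    def test_decision_function_matches_stored_weights(self, separable_toy):
        X, y = separable_toy
        for m in hv.train_ova_svms(X, y):
            assert m.decision_value(X[0]) == pytest.approx(
                float(m.w @ X[0] + m.b)
            )

    def test_tiny_class_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["control", "SS", "SS"])
        with pytest.raises(ValueError):
            hv.train_ova_svms(X, y)


class TestOVAPredict:
    @staticmethod
    def _model(cls, w, b):
        return BinarySVMModel(w=np.asarray(w, float), b=b, C=1.0,
                              positive_class=cls)

    def test_argmax_decision(self):
        models = [self._model("control", [0.0], 0.5),
                  self._model("SS", [0.0], -0.2),
                  self._model("LS", [0.0], -0.9)]
        assert hv.ova_predict(models, np.array([0.0])) == "control"

    def test_tie_breaks_to_first_class_in_fixed_order(self):
        models = [self._model(c, [0.0], 1.0) for c in ("control", "SS", "LS")]
        assert hv.ova_predict(models, np.array([0.0])) == "control"

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            hv.ova_predict([self._model("SS", [1.0, 2.0], 0.0)],
                           np.array([1.0]))


class TestRankingScores:
    def test_worked_two_feature_example(self):
        models = [
            BinarySVMModel(w=np.array(w), b=0.0, C=1.0, positive_class=c)
            for c, w in [("control", [0.3, 0.1]), ("SS", [0.2, 0.5]),
                         ("LS", [0.1, 0.2])]
        ]
        assert np.allclose(hv.ranking_scores(models), [0.09, 0.25])

    def test_single_model_is_elementwise_square(self):
        m = BinarySVMModel(w=np.array([0.5, -2.0]), b=0.0, C=1.0,
                           positive_class="SS")
        assert np.allclose(hv.ranking_scores([m]), [0.25, 4.0])

    @given(
        W=hnp.arrays(float, (5, 8),
                     elements=st.floats(-10, 10, allow_nan=False)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_exhaustive_double_loop(self, W):
        models = [
            BinarySVMModel(w=W[r], b=0.0, C=1.0, positive_class=str(r))
            for r in range(W.shape[0])
        ]
        J = hv.ranking_scores(models)
        oracle = [max(W[r, j] ** 2 for r in range(W.shape[0]))
                  for j in range(W.shape[1])]
        assert np.allclose(J, oracle)

    def test_dimension_mismatch_raises(self):
        models = [
            BinarySVMModel(w=np.array([1.0]), b=0.0, C=1.0, positive_class="a"),
            BinarySVMModel(w=np.array([1.0, 2.0]), b=0.0, C=1.0,
                           positive_class="b"),
        ]
        with pytest.raises(ValueError):
            hv.ranking_scores(models)


class TestSVMRFE:
    def test_full_ranking_is_a_permutation_with_ten_eliminations(
        self, calibrated_table, calibrated_ranking
    ):
        rk = calibrated_ranking
        assert sorted(rk.rank_order) == sorted(hv.FEATURE_NAMES)
        assert len(rk.elimination_order) == 10
        assert rk.iteration_weights["iteration"].max() == 10

    def test_single_feature_is_trivially_ranked(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1], [2.0], [2.1]])
        y = np.array(["control", "control", "SS", "SS", "LS", "LS"])
        rk = hv.rfe_rank(X, y, feature_names=["only"])
        assert rk.rank_order == ["only"]
        assert rk.elimination_order == []

    def test_iteration_t_has_d_minus_t_plus_one_survivors(self, calibrated_ranking):
        w = calibrated_ranking.iteration_weights
        for t, sub in w[w["model"] == "max"].groupby("iteration"):
            assert sub["feature"].nunique() == 11 - (t - 1)

    def test_recorded_model_weights_have_unit_norm(self, calibrated_ranking):
        w = calibrated_ranking.iteration_weights
        per_model = w[w["model"] != "max"]
        norms = per_model.groupby(["iteration", "model"])["weight"].apply(
            lambda s: np.sqrt((s**2).sum())
        )
        assert np.allclose(norms, 1.0)

    def test_informative_features_outrank_noise(self):
        """2 class-separated + 2 pure-noise features: informatives on top."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = [], []
            for k, label in enumerate(hv.CLASS_ORDER):
                n = 20
                block = np.column_stack([
                    rng.normal(3.0 * k, 1.0, n),       # informative
                    rng.normal(3.0 * ((k + 1) % 3), 1.0, n),  # informative
                    rng.normal(0.0, 1.0, n),           # noise
                    rng.normal(0.0, 1.0, n),           # noise
                ])
                X.append(block)
                y += [label] * n
            rk = hv.rfe_rank(np.vstack(X), np.array(y),
                             feature_names=["inf1", "inf2", "noise1", "noise2"])
            wins += set(rk.rank_order[:2]) == {"inf1", "inf2"}
        assert wins >= 9

    def test_column_permutation_permutes_ranking(self, calibrated_table):
        df = calibrated_table
        perm = ["nLF", "mRR", "CVRR", "pNN5", "SDRR", "lnHF", "mHR",
                "nHF", "RMSSD", "lnLFHF", "lnLF"]
        a = hv.SVMRFE.from_dataframe(df).fit()
        b = hv.SVMRFE.from_dataframe(df, feature_cols=perm).fit()
        assert a.rank_order == b.rank_order

    def test_elimination_tie_breaks_to_latest_canonical_feature(self):
        # duplicated column: identical J; the later copy must go first
        X = np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0],
                      [1.1, 1.1], [2.0, 2.0], [2.1, 2.1]])
        y = np.array(["control", "control", "SS", "SS", "LS", "LS"])
        rk = hv.rfe_rank(X, y, feature_names=["orig", "copy"])
        assert rk.elimination_order[0] == "copy"

    def test_results_summary_and_top_prefix(self, calibrated_ranking):
        rk = calibrated_ranking
        assert rk.top(3) == rk.rank_order[:3]
        assert "rank" in rk.summary()
        with pytest.raises(ValueError):
            rk.top(0)

    def test_ranking_is_deterministic(self, calibrated_table):
        a = hv.SVMRFE.from_dataframe(calibrated_table).fit()
        b = hv.SVMRFE.from_dataframe(calibrated_table).fit()
        assert a.rank_order == b.rank_order
        assert a.iteration_weights.equals(b.iteration_weights)
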