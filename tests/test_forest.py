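"""Bagged-tree training, OOB diagnostics, reduction and aggregation."""

import numpy as np
import pandas as pd
import pytest

import vsdwave.synthdata as sd
from vsdwave.forest import (
    PredictionSet,
    SplitSpec,
    aggregate_recording,
    predict,
    reduce_model,
    stratified_split,
    train_forest,
    vote_aggregation_simulation,
)


def table_from_arrays(X, y, feature_names=None, rec_ids=None):
    feature_names = feature_names or sd.FEATURES[: X.shape[1]]
    df = pd.DataFrame(X, columns=feature_names)
    df["label"] = y
    df["recording_id"] = rec_ids if rec_ids is not None else "r1"
    return df


def separable_table(n_per_class=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, 3))
    X[:n_per_class, 0] += 10.0  # feature 0 separates perfectly
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return table_from_arrays(X, y, feature_names=["f0", "f1", "f2"])


class TestStratifiedSplit:
    def test_rounded_33_percent_of_printed_totals(self, default_table):
        table, _ = default_table
        train, valid = stratified_split(table, SplitSpec(fraction=0.33, seed=1))
        tc = train["label"].value_counts()
        assert (tc["control"], tc["propranolol"], tc["isoproterenol"]) == (48, 33, 70)
        vc = valid["label"].value_counts()
        assert (vc["control"], vc["propranolol"], vc["isoproterenol"]) == (97, 67, 142)

    def test_explicit_counts_give_308_validation_rows(self, default_table):
        table, _ = default_table
        spec = SplitSpec(
            per_class_counts={"control": 45, "propranolol": 34, "isoproterenol": 70},
            seed=1,
        )
        train, valid = stratified_split(table, spec)
        assert len(train) == 149
        assert len(valid) == 308
        vc = valid["label"].value_counts()
        assert (vc["control"], vc["propranolol"], vc["isoproterenol"]) == (100, 66, 142)

    def test_even_split_disjoint_union(self):
        rng = np.random.default_rng(0)
        table = table_from_arrays(
            rng.normal(size=(20, 2)), ["a"] * 10 + ["b"] * 10, ["h_max", "w"]
        )
        train, valid = stratified_split(table, SplitSpec(fraction=0.5, seed=0))
        assert train["label"].value_counts().tolist() == [5, 5]
        merged = pd.concat([train, valid]).sort_values(["h_max", "w"])
        original = table.sort_values(["h_max", "w"])
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True), original.reset_index(drop=True)
        )

    def test_tiny_class_rejected(self):
        table = table_from_arrays(np.zeros((3, 2)), ["a", "a", "b"], ["h_max", "w"])
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(table, SplitSpec())


class TestTrainForest:
    def test_separable_feature_dominates(self):
        model = train_forest(separable_table(), seed=3, feature_names=["f0", "f1", "f2"])
        assert model.oob_error < 0.05
        assert model.importances.idxmax() == "f0"
        assert model.importances["f0"] > model.importances[["f1", "f2"]].max()

    def test_permuted_labels_show_no_skill(self, default_table):
        """Label-permuted training carries no class information: OOB accuracy
        sits in the chance band between the match-the-neighbour rate
        (sum of squared priors, ~35.5%) and the majority-class rate (46.4%),
        and never above it.  Bagged deep trees mirror nearest-neighbour
        labels, so their chance level is below the majority rate."""
        table, _ = default_table
        priors = np.array([145, 100, 212]) / 457
        floor = float((priors**2).sum()) - 0.05
        ceiling = float(priors.max()) + 0.05
        for s in (42, 99):
            rng = np.random.default_rng(s)
            shuffled = table.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            model = train_forest(shuffled, seed=s)
            assert floor <= (1 - model.oob_error) <= ceiling

    def test_reproducible_given_seed(self, default_split):
        train, valid = default_split
        m1 = train_forest(train, seed=9)
        m2 = train_forest(train, seed=9)
        np.testing.assert_array_equal(m1.oob_error_curve, m2.oob_error_curve)
        pd.testing.assert_series_equal(m1.importances, m2.importances)
        p1, p2 = predict(m1, valid), predict(m2, valid)
        pd.testing.assert_frame_equal(p1.frame, p2.frame)

    def test_oob_error_estimates_heldout_error(self, trained_default):
        model, train, valid = trained_default
        preds = predict(model, valid)
        heldout_err = np.mean(preds.predicted.to_numpy() != valid["label"].to_numpy())
        assert abs(model.oob_error - heldout_err) < 0.10

    def test_oob_curve_stabilizes_by_50_trees(self, default_split):
        train, _ = default_split
        big = train_forest(train, n_trees=500, seed=11)
        assert abs(big.oob_error_curve[49] - big.oob_error_curve[499]) < 0.06

    def test_single_class_rejected(self):
        table = table_from_arrays(np.random.default_rng(0).normal(size=(20, 2)),
                                  ["a"] * 20, ["h_max", "w"])
        with pytest.raises(ValueError, match="2 classes"):
            train_forest(table, feature_names=["h_max", "w"])


class TestPredict:
    def test_memorized_point_scores_one(self):
        table = separable_table()
        model = train_forest(table, seed=5, feature_names=["f0", "f1", "f2"])
        preds = predict(model, table.iloc[[0]])
        assert preds.predicted.iloc[0] == "a"
        assert preds.frame["score_a"].iloc[0] == pytest.approx(1.0)

    def test_scores_normalized(self, trained_default):
        model, _, valid = trained_default
        preds = predict(model, valid)
        sums = preds.scores().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert (preds.scores().to_numpy() >= 0).all()

    def test_missing_feature_named(self, trained_default):
        model, _, valid = trained_default
        with pytest.raises(ValueError, match="h_max"):
            predict(model, valid.drop(columns=["h_max"]))


class TestReduceModel:
    def noisy_table(self, seed=0, n=420):
        """Three informative metrics plus two pure-noise features."""
        rng = np.random.default_rng(seed)
        y = np.repeat(["a", "b", "c"], n // 3)
        shift = {"a": 0.0, "b": 1.4, "c": 2.8}
        X = rng.normal(size=(n, 5))
        for j in range(3):
            X[:, j] += [shift[c] for c in y]
        names = ["s1", "s2", "s3", "noise1", "noise2"]
        return table_from_arrays(X, y, feature_names=names), names

    def test_noise_features_removed_first(self):
        table, names = self.noisy_table()
        train, valid = stratified_split(table, SplitSpec(seed=2))
        report, final = reduce_model(train, valid, seed=2, feature_names=names)
        step1 = report.steps[1]
        assert set(step1.removed) == {"noise1", "noise2"}
        acc0 = report.steps[0].validation_accuracy
        assert abs(step1.validation_accuracy - acc0) <= 0.05

    def test_all_above_threshold_is_noop(self):
        table, names = self.noisy_table()
        train, valid = stratified_split(table, SplitSpec(seed=2))
        report, _ = reduce_model(
            train, valid, seed=2, importance_threshold=-10.0, feature_names=names
        )
        # no threshold step: step 1 already removes a single weakest feature
        assert len(report.steps[1].removed) == 1

    def test_reduction_stops_above_two_features(self, default_split):
        train, valid = default_split
        report, final = reduce_model(train, valid, seed=1)
        assert len(final.feature_names) >= 2
        assert report.final_features == final.feature_names

    def test_two_feature_model_weaker_than_three(self, default_split):
        """Forcing removal down to 2 features costs accuracy vs 3 features."""
        train, valid = default_split
        cfg_seed = sd.default_config().seed
        m5 = train_forest(train, seed=cfg_seed)
        order = m5.importances.sort_values().index.tolist()
        feats3 = [f for f in m5.feature_names if f not in order[:2]]
        feats2 = [f for f in m5.feature_names if f not in order[:3]]

        def acc(feats):
            m = train_forest(train, seed=cfg_seed, feature_names=feats)
            p = predict(m, valid)
            return np.mean(p.predicted.to_numpy() == valid["label"].to_numpy())

        assert acc(feats2) < acc(feats3)


class TestAggregateRecording:
    def make_preds(self, calls, scores=None, rec="r1", classes=("a", "b", "c")):
        frame = pd.DataFrame({"predicted": calls, "recording_id": rec})
        for i, c in enumerate(classes):
            if scores is None:
                frame[f"score_{c}"] = (np.asarray(calls) == c).astype(float)
            else:
                frame[f"score_{c}"] = scores[:, i]
        return PredictionSet(frame=frame, classes=np.array(classes))

    def test_unanimous(self):
        agg = aggregate_recording(self.make_preds(["b"] * 8))
        assert agg.loc["r1", "predicted"] == "b"

    def test_tie_broken_by_mean_score(self):
        scores = np.array(
            [[0.48, 0.46, 0.06], [0.48, 0.46, 0.06], [0.46, 0.48, 0.06], [0.44, 0.50, 0.06]]
        )
        preds = self.make_preds(["a", "a", "b", "b"], scores=scores)
        agg = aggregate_recording(preds)
        # votes tied 2-2; class a has the higher mean score (0.465 vs 0.475? no:
        # a: mean 0.465, b: mean 0.475) -> b wins
        assert agg.loc["r1", "predicted"] == "b"

    def test_multinomial_aggregation_near_perfect(self):
        accuracy = vote_aggregation_simulation(
            n_recordings=1000, n_waveforms=60, p_correct=0.6, seed=17
        )
        assert accuracy > 99.9

    def test_aggregation_beats_waveform_accuracy(self):
        """With per-waveform accuracy 0.55 > 1/2, majority vote improves on it."""
        accuracy = vote_aggregation_simulation(
            n_recordings=400, n_waveforms=31, p_correct=0.55, seed=23
        )
        assert accuracy / 100.0 > 0.55
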