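"""Split protocol, budgeted ensemble training, repeat evaluation,
prediction, importance and partial dependence, bundle persistence."""

import warnings

import numpy as np
import pandas as pd
import pytest

import synthdiff as sd
from synthdiff.model import (
    HARD_THRESHOLD,
    ModelBundle,
    PredictionRow,
    SplitSpec,
    decode_labels,
    evaluate_bundle,
    load_bundle,
    save_bundle,
    split_dataset,
    train_model,
)
from synthdiff.manifest import MANIFEST_VERSION
from synthdiff.seqio import EASY, HARD, SequenceRecord
from synthdiff.simulate import informative_noise_matrix


@pytest.fixture(scope="module")
def planted_split():
    X, labels, informative = informative_noise_matrix(n_rows=160, seed=9)
    tr, te = split_dataset(list(X.index), SplitSpec(seed=0))
    lab = dict(zip(X.index, labels))
    return (
        X.loc[tr], [lab[i] for i in tr],
        X.loc[te], [lab[i] for i in te],
        informative,
    )


@pytest.fixture(scope="module")
def fitted(planted_split):
    Xtr, ytr, Xte, yte, informative = planted_split
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = train_model(Xtr, ytr, seed=0, budget_iterations=8)
    return bundle, Xte, yte, informative


class TestSplit:
    def test_three_to_one_split_of_1076(self):
        tr, te = split_dataset(1076, SplitSpec(test_fraction=0.25, seed=0))
        assert (len(tr), len(te)) == (807, 269)

    def test_minimal_split(self):
        tr, te = split_dataset(4, SplitSpec(test_fraction=0.25, seed=0))
        assert (len(tr), len(te)) == (3, 1)

    def test_same_seed_same_partition(self):
        a = split_dataset(100, SplitSpec(seed=3))
        b = split_dataset(100, SplitSpec(seed=3))
        assert a == b
        c = split_dataset(100, SplitSpec(seed=4))
        assert a != c

    def test_degenerate_fraction_errors(self):
        with pytest.raises(ValueError):
            split_dataset(10, SplitSpec(test_fraction=0.01))
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=1.5)

    def test_single_class_partition_warns(self):
        labels = [HARD] * 1 + [EASY] * 19
        with pytest.warns(UserWarning, match="single class"):
            split_dataset(list(range(20)), SplitSpec(seed=1), labels=labels)


class TestTrainModel:
    def test_weights_positive_and_sum_to_one(self, fitted):
        bundle, *_ = fitted
        w = [x[2] for x in bundle.ensemble]
        assert all(v > 0 for v in w)
        assert sum(w) == pytest.approx(1.0)

    def test_separable_data_scores_high_held_out(self, fitted):
        bundle, Xte, yte, _ = fitted
        assert evaluate_bundle(bundle, Xte, yte).F1 >= 0.95

    def test_same_seed_and_cap_reproduce_the_ensemble(self, planted_split):
        Xtr, ytr, *_ = planted_split
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = train_model(Xtr, ytr, seed=5, budget_iterations=6)
            b2 = train_model(Xtr, ytr, seed=5, budget_iterations=6)
        assert [(f, w) for f, _, w in b1.ensemble] == [(f, w) for f, _, w in b2.ensemble]
        X = Xtr.to_numpy()
        assert np.allclose(b1.hard_probability(X), b2.hard_probability(X))

    def test_single_class_labels_error(self, planted_split):
        Xtr, *_ = planted_split
        with pytest.raises(ValueError, match="single class"):
            train_model(Xtr, [HARD] * len(Xtr), seed=0, budget_iterations=2)

    def test_zero_budget_error(self, planted_split):
        Xtr, ytr, *_ = planted_split
        with pytest.raises(ValueError, match="budget"):
            train_model(Xtr, ytr, budget_iterations=0)


class _FixedProb:
    """Stub learner returning a constant HARD probability."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


def _toy_bundle(p1, p2, w1, features=("f0", "f1")):
    return ModelBundle(
        ensemble=[("a", _FixedProb(p1), w1), ("b", _FixedProb(p2), 1 - w1)],
        normalizer=None,
        feature_names=list(features),
        manifest_version=MANIFEST_VERSION,
    )


class TestEnsembleContract:
    def test_prediction_is_weight_averaged_probability(self):
        bundle = _toy_bundle(0.9, 0.1, 0.25)
        X = np.zeros((3, 2))
        assert np.allclose(bundle.hard_probability(X), 0.25 * 0.9 + 0.75 * 0.1)

    def test_tie_probability_goes_to_hard(self):
        bundle = _toy_bundle(0.5, 0.5, 0.5)
        assert decode_labels(bundle.predict_from_selected(np.zeros((1, 2)))) == [HARD]
        assert HARD_THRESHOLD == 0.5

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ModelBundle(
                ensemble=[("a", _FixedProb(0.5), 0.5)],
                normalizer=None,
                feature_names=["f0"],
                manifest_version=MANIFEST_VERSION,
            )


class TestRepeatEvaluate:
    def test_ten_runs_recorded_with_ordered_stats(self, planted_split):
        Xtr, ytr, Xte, yte, _ = planted_split
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = sd.repeat_evaluate(
                Xtr, ytr, Xte, yte, n_repeats=10, seed=0, budget_iterations=3
            )
        assert len(report.runs) == 10
        stats = report.stats()
        for m in ("F1", "MCC", "CK"):
            row = stats.loc[m]
            assert row["min"] <= row["mean"] <= row["max"]
            assert row["std"] >= 0

    def test_single_repeat_rejected(self, planted_split):
        Xtr, ytr, Xte, yte, _ = planted_split
        with pytest.raises(ValueError):
            sd.repeat_evaluate(Xtr, ytr, Xte, yte, n_repeats=1)


class TestImportanceAndDependence:
    def test_informative_features_dominate_noise(self, fitted):
        bundle, Xte, yte, informative = fitted
        imp = sd.permutation_importance(bundle, Xte, yte, n_shuffles=5, seed=0)
        top = set(imp.index[: len(informative)])
        assert len(top & set(informative)) >= 3
        noise = imp.loc[[i for i in imp.index if i.startswith("noise")]]
        # pure-noise features have importance indistinguishable from zero
        assert (noise["mean_decrease"].abs()
                <= 2 * noise["std_decrease"] + 1e-9).mean() > 0.8

    def test_importance_is_deterministic(self, fitted):
        bundle, Xte, yte, _ = fitted
        a = sd.permutation_importance(bundle, Xte, yte, n_shuffles=3, seed=2)
        b = sd.permutation_importance(bundle, Xte, yte, n_shuffles=3, seed=2)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            sd.permutation_importance(bundle, Xte, yte, n_shuffles=0)

    def test_constant_model_has_flat_curve(self):
        bundle = _toy_bundle(0.7, 0.7, 0.5)
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)), columns=["f0", "f1"])
        grid, curve = sd.partial_dependence(bundle, X, "f0", grid_points=7)
        assert len(grid) == len(curve) == 7
        assert np.allclose(curve, 0.7)
        assert grid[0] == X["f0"].min() and grid[-1] == X["f0"].max()

    def test_monotone_planted_rule_gives_nondecreasing_curve(self, fitted):
        bundle, Xte, yte, informative = fitted
        grid, curve = sd.partial_dependence(bundle, Xte, informative[0], grid_points=9)
        assert curve[-1] > curve[0]
        assert (np.diff(curve) >= -0.05).all()  # non-decreasing up to ensemble noise

    def test_unknown_feature_rejected(self, fitted):
        bundle, Xte, *_ = fitted
        with pytest.raises(KeyError):
            sd.partial_dependence(bundle, Xte, "no_such_feature")


class TestPersistence:
    def test_round_trip_preserves_predictions(self, fitted, tmp_path):
        bundle, Xte, _, _ = fitted
        p = tmp_path / "bundle.joblib"
        save_bundle(bundle, p)
        back = load_bundle(p)
        X = Xte.to_numpy()
        assert np.array_equal(bundle.hard_probability(X), back.hard_probability(X))

    def test_version_mismatch_rejected(self, fitted, tmp_path):
        import joblib

        bundle, *_ = fitted
        p = tmp_path / "bundle.joblib"
        save_bundle(bundle, p)
        payload = joblib.load(p)
        payload["manifest_version"] = "0.0"
        joblib.dump(payload, p)
        with pytest.raises(ValueError, match="manifest version"):
            load_bundle(p)

    def test_missing_and_corrupt_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_bundle(tmp_path / "nope.joblib")
        bad = tmp_path / "bad.joblib"
        bad.write_text("not a bundle")
        with pytest.raises(ValueError):
            load_bundle(bad)


class TestModelResultsApi:
    def test_fit_returns_results_with_summary(self, small_dataset):
        model = sd.SynthesisDifficultyModel.from_dataset(small_dataset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(seed=0, budget_iterations=6)
        text = res.summary()
        assert "held-out F1" in text
        assert "ensemble composition" in text
        assert res.test_metrics.F1 >= 0.8  # planted difficulty is learnable

    def test_predict_records_end_to_end(self, small_dataset):
        model = sd.SynthesisDifficultyModel.from_dataset(small_dataset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(seed=0, budget_iterations=6)
        records = small_dataset.records[:5] + [SequenceRecord("bad", "ACGT")]
        rows = res.predict(records)
        assert [r.id for r in rows] == [r.id for r in records]
        assert all(r.error is None for r in rows[:5])
        assert rows[-1].error is not None  # too short to extract
        for r in rows[:5]:
            assert r.label in (EASY, HARD)
            assert 0 <= r.hard_probability <= 1
            assert len(r.features) == len(res.bundle.feature_names)
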