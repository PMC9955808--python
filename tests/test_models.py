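"""Classifier specs, cross-validation, grid search and the cascade rules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from masgrade import models as md
from masgrade.dataset import fit_scaler
from masgrade.features import FEATURE_NAMES
from tests.conftest import make_feature_table


class TestMakeClassifier:
    def test_svm_defaults(self):
        clf = md.make_classifier(md.ClassifierSpec.default("svm"), seed=1)
        assert clf.C == 15 and clf.kernel == "rbf" and clf.gamma == "scale"

    def test_random_forest_defaults(self):
        clf = md.make_classifier(md.ClassifierSpec.default("random_forest"), seed=1)
        assert clf.n_estimators == 25 and clf.criterion == "gini"
        assert clf.max_features == 3 and clf.min_samples_leaf == 3

    def test_gnb_variance_smoothing(self):
        clf = md.make_classifier(md.ClassifierSpec.default("gaussian_nb"))
        assert clf.var_smoothing == pytest.approx(0.1203)

    def test_typo_hyperparameter_rejected(self):
        spec = md.ClassifierSpec(family="svm", hyperparameters={"kernle": "rbf"})
        with pytest.raises(ValueError, match="kernle"):
            md.make_classifier(spec)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            md.make_classifier(md.ClassifierSpec(family="mlp"))

    @pytest.mark.parametrize("family", md.FAMILIES)
    def test_all_families_fit_and_predict_strings(self, family):
        table = make_feature_table({"0": 8, "1": 8}, seed=1, separated=True)
        clf = md.make_classifier(md.ClassifierSpec.default(family), seed=0)
        X = table[list(FEATURE_NAMES)].to_numpy()
        y = table["mas_label"].to_numpy()
        clf.fit(X, y)
        assert set(clf.predict(X)) <= {"0", "1"}


class TestCrossval:
    def test_separable_blobs_score_one(self):
        table = make_feature_table({"0": 10, "1": 10, "2": 10}, separated=True)
        mean, std = md.crossval_balanced_accuracy(
            md.ClassifierSpec.default("svm"), table, k=5, seed=0
        )
        assert mean == pytest.approx(1.0) and std == pytest.approx(0.0)

    def test_balanced_classes_equal_plain_accuracy_per_fold(self):
        # with equal class sizes and stratified folds, balanced accuracy
        # coincides with plain accuracy on every fold
        table = make_feature_table({"0": 12, "1": 12}, seed=21)
        X = table[list(FEATURE_NAMES)].to_numpy()
        y = table["mas_label"].to_numpy()
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        for tr, te in skf.split(X, y):
            clf = md.make_classifier(md.ClassifierSpec.default("gaussian_nb"), seed=0)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            assert balanced_accuracy_score(y[te], pred) == pytest.approx(
                np.mean(pred == y[te])
            )

    def test_matches_manual_two_fold_computation(self):
        table = make_feature_table({"0": 4, "1": 4}, seed=2)
        spec = md.ClassifierSpec.default("gaussian_nb")
        mean, std = md.crossval_balanced_accuracy(spec, table, k=2, seed=7)
        X = table[list(FEATURE_NAMES)].to_numpy()
        y = table["mas_label"].to_numpy()
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=7)
        scores = []
        for tr, te in skf.split(X, y):
            clf = md.make_classifier(spec, seed=7)
            clf.fit(X[tr], y[tr])
            scores.append(balanced_accuracy_score(y[te], clf.predict(X[te])))
        assert mean == pytest.approx(np.mean(scores))
        assert std == pytest.approx(np.std(scores))

    def test_class_too_small_for_folds(self):
        table = make_feature_table({"0": 12, "1": 3})
        with pytest.raises(ValueError, match="smaller k"):
            md.crossval_balanced_accuracy(
                md.ClassifierSpec.default("svm"), table, k=10
            )


class TestGridSearch:
    def test_single_point_grid_returned(self):
        table = make_feature_table({"0": 8, "1": 8}, separated=True)
        best, scores = md.grid_search(
            "svm", table, param_grid={"C": [2.5]}, k=2, seed=0
        )
        assert best.hyperparameters == {"C": 2.5}
        assert len(scores) == 1

    def test_score_table_rows_equal_grid_product(self):
        table = make_feature_table({"0": 8, "1": 8}, separated=True)
        _, scores = md.grid_search(
            "svm",
            table,
            param_grid={"C": [0.1, 1, 10], "kernel": ["linear", "rbf"]},
            k=2,
            seed=0,
        )
        assert len(scores) == 6

    def test_underfitting_c_loses_on_separable_toy(self):
        # with unbalanced classes, a vanishingly small C collapses the SVM
        # to the majority vote (balanced accuracy 0.5); large C must win
        table = make_feature_table({"0": 24, "1": 6}, seed=5, separated=True)
        best, _ = md.grid_search(
            "svm", table, param_grid={"C": [1e-4, 10.0]}, k=3, seed=0
        )
        assert best.hyperparameters["C"] == 10.0

    def test_empty_grid_rejected(self):
        table = make_feature_table({"0": 8, "1": 8})
        with pytest.raises(ValueError, match="empty"):
            md.grid_search("svm", table, param_grid={"C": []})


FIVE = {"0": 8, "1": 8, "1+": 8, "2": 8, "3": 8}


class _StubModel:
    """Fixed-output stand-in for a trained classifier (rule-trace tests)."""

    def __init__(self, label=None, classes=None, proba=None):
        self._label = label
        self.classes_ = np.array(classes if classes else ["0", "1", "1+", "2", "3"])
        self._proba = proba

    def predict(self, X):
        return np.array([self._label] * len(X))

    def predict_proba(self, X):
        return np.tile(np.asarray(self._proba), (len(X), 1))


def _stub_cascade(svm_label="2", rf_proba=(0.2, 0.2, 0.2, 0.2, 0.2)):
    table = make_feature_table(FIVE, seed=1)
    scaler = fit_scaler(table)
    return md.CascadeModel(
        rom_threshold=10.0,
        svm=_StubModel(label=svm_label),
        rf=_StubModel(classes=["0", "1", "1+", "2", "3"], proba=rf_proba),
        scaler=scaler,
    )


def _features(value=1.0):
    return {name: value for name in FEATURE_NAMES}


class TestCascadeRules:
    def test_rom_below_threshold_is_mas4(self):
        model = _stub_cascade()
        assert md.predict_cascade(model, _features(), rom=7.09) == "4"

    def test_rom_exactly_ten_delegates_to_classifiers(self):
        # the rule reads "smaller than 10 degrees": 10.0 is not MAS 4
        model = _stub_cascade(svm_label="1")
        assert md.predict_cascade(model, _features(), rom=10.0) == "1"

    @pytest.mark.parametrize("label", ["1", "3"])
    def test_svm_accepted_only_for_its_grades(self, label):
        model = _stub_cascade(svm_label=label)
        assert md.predict_cascade(model, _features(), rom=90.0) == label

    def test_svm_rejected_falls_through_to_rf(self):
        # SVM votes "2" (not in its accepted set) -> masked RF probabilities
        # over ("0", "1+", "2") are (0.2, 0.5, 0.3) -> "1+"
        model = _stub_cascade(
            svm_label="2", rf_proba=(0.2, 0.0, 0.5, 0.3, 0.0)
        )
        assert md.predict_cascade(model, _features(), rom=90.0) == "1+"

    def test_rf_stage_never_emits_svm_grades(self):
        # RF puts almost all mass on "1" and "3", which the mask removes
        model = _stub_cascade(svm_label="0", rf_proba=(0.01, 0.48, 0.01, 0.01, 0.49))
        out = md.predict_cascade(model, _features(), rom=90.0)
        assert out in {"0", "1+", "2"}

    def test_rf_tie_breaks_toward_lower_grade(self):
        model = _stub_cascade(svm_label="2", rf_proba=(0.4, 0.0, 0.4, 0.2, 0.0))
        assert md.predict_cascade(model, _features(), rom=90.0) == "0"

    def test_nan_feature_rejected(self):
        model = _stub_cascade()
        bad = _features()
        bad["rom"] = float("nan")
        with pytest.raises(ValueError, match="finite"):
            md.predict_cascade(model, bad, rom=90.0)

    def test_class_set_invariants_enforced(self):
        table = make_feature_table(FIVE, seed=1)
        with pytest.raises(ValueError, match="disjoint"):
            md.CascadeModel(
                rom_threshold=10.0,
                svm=_StubModel(label="1"),
                rf=_StubModel(),
                scaler=fit_scaler(table),
                svm_accept_set=("1", "3"),
                rf_allowed_set=("0", "1", "2"),
            )


class TestTrainCascade:
    def test_trains_and_closes_over_five_grades(self):
        table = make_feature_table(FIVE, seed=3, separated=True)
        model = md.train_cascade(table, seed=0)
        X = (
            table[list(FEATURE_NAMES)].to_numpy()
            - np.array([model.scaler.mean[n] for n in FEATURE_NAMES])
        ) / np.array([model.scaler.std[n] for n in FEATURE_NAMES])
        assert set(model.svm.predict(X)) == set(FIVE)
        assert set(model.rf.predict(X)) == set(FIVE)

    def test_same_seed_identical_predictions(self):
        table = make_feature_table(FIVE, seed=3)
        probe = make_feature_table(FIVE, seed=99)
        m1 = md.train_cascade(table, seed=11)
        m2 = md.train_cascade(table, seed=11)
        p1 = [
            md.predict_cascade(m1, row[list(FEATURE_NAMES)].to_dict(), rom=50.0)
            for _, row in probe.iterrows()
        ]
        p2 = [
            md.predict_cascade(m2, row[list(FEATURE_NAMES)].to_dict(), rom=50.0)
            for _, row in probe.iterrows()
        ]
        assert p1 == p2

    def test_mas4_row_rejected(self):
        table = make_feature_table({**FIVE, "4": 2})
        with pytest.raises(ValueError, match="MAS 4"):
            md.train_cascade(table, seed=0)

    def test_missing_class_listed(self):
        table = make_feature_table({"0": 8, "1": 8, "1+": 8, "2": 8})
        with pytest.raises(ValueError, match="'3'"):
            md.train_cascade(table, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        table = make_feature_table(FIVE, seed=3)
        model = md.train_cascade(table, seed=0)
        md.save_cascade(model, tmp_path / "cascade.pkl")
        back = md.load_cascade(tmp_path / "cascade.pkl")
        assert back.rom_threshold == model.rom_threshold
        assert back.scaler == model.scaler
        feats = _features(0.5)
        assert md.predict_cascade(back, feats, rom=50.0) == md.predict_cascade(
            model, feats, rom=50.0
        )

    def test_batch_prediction_never_breaks_role_restriction(self):
        table = make_feature_table(FIVE, seed=3)
        model = md.train_cascade(table, seed=0)
        probe = make_feature_table({**FIVE, "4": 4}, seed=55)
        probe.loc[probe.mas_label == "4", "rom"] = 5.0
        out = md.predict_cascade_frame(model, probe)
        assert set(out) <= {"0", "1", "1+", "2", "3", "4"}
        assert (out[probe["rom"] < 10.0] == "4").all()
        assert (out[probe["rom"] >= 10.0] != "4").all()
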