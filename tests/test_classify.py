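"""Splitting, forward-selection SVM, confusion metrics and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest

from peptidome.classify import (
    ClassifierModel,
    ConfusionMatrix,
    cross_validated_report,
    evaluate,
    forward_select_svm,
    roc_auc,
    split_train_validation,
)
from peptidome.synthetic import SimulationConfig, simulate_feature_matrix


def _metadata(counts: dict) -> pd.DataFrame:
    rows = []
    for group, n in counts.items():
        rows += [(f"{group[:2]}{i:03d}", group) for i in range(n)]
    md = pd.DataFrame(rows, columns=["subject_id", "group"]).set_index("subject_id")
    md["age"] = 50.0
    return md


class TestSplit:
    def test_balanced_small_split(self):
        md = _metadata({"ccRCC": 10, "control": 10})
        train, val = split_train_validation(md, 0.6, seed=1)
        assert len(train) == 12 and len(val) == 8
        groups = md.loc[train, "group"].value_counts()
        assert groups["ccRCC"] == 6 and groups["control"] == 6
        assert set(train).isdisjoint(val)
        assert set(train) | set(val) == set(md.index)

    def test_deterministic_given_seed(self):
        md = _metadata({"ccRCC": 15, "control": 20})
        assert split_train_validation(md, seed=5) == split_train_validation(md, seed=5)
        assert split_train_validation(md, seed=5) != split_train_validation(md, seed=6)

    def test_study_sized_split_reproduces_validation_counts(self):
        """153 negatives + 137 positives at ~60% -> validation 61 + 55."""
        md = _metadata({"control": 153, "ccRCC": 137})
        train, val = split_train_validation(md, 0.6, seed=0)
        counts = md.loc[val, "group"].value_counts()
        assert counts["control"] == 61
        assert counts["ccRCC"] == 55

    def test_singleton_class_rejected(self):
        md = _metadata({"ccRCC": 1, "control": 10})
        with pytest.raises(ValueError, match="1 subject"):
            split_train_validation(md)


class TestConfusionMatrix:
    @pytest.mark.parametrize(
        "cm,decimals,sens,spec,ppv,npv",
        [
            # published ccRCC-vs-controls whole-cohort CV table (2 decimals)
            (ConfusionMatrix(tp=97, fp=14, tn=123, fn=21), 2,
             82.20, 89.78, 87.39, 85.42),
            # published malignant-vs-rest validation table (1-decimal style)
            (ConfusionMatrix(tp=42, fp=8, tn=53, fn=13), 1,
             76.4, 86.9, 84.0, 80.3),
        ],
    )
    def test_metrics_reproduce_reference_values(self, cm, decimals, sens, spec, ppv, npv):
        assert round(cm.sensitivity, decimals) == pytest.approx(sens)
        assert round(cm.specificity, decimals) == pytest.approx(spec)
        assert round(cm.ppv, decimals) == pytest.approx(ppv)
        assert round(cm.npv, decimals) == pytest.approx(npv)

    def test_all_correct_gives_100_everywhere(self):
        cm = ConfusionMatrix(tp=5, fp=0, tn=7, fn=0)
        assert cm.metrics() == {"sensitivity_pct": 100.0, "specificity_pct": 100.0,
                                "ppv_pct": 100.0, "npv_pct": 100.0}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=0, fn=0)


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        points, auc = roc_auc([3.0, 2.0, -1.0, -2.0], [True, True, False, False])
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_constant_confidence_auc_half(self):
        _, auc = roc_auc([1.0] * 6, [True, False, True, False, True, False])
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        """AUC = (concordant + ties/2) / (n+ * n-), counted exhaustively."""
        rng = np.random.default_rng(3)
        conf = np.round(rng.normal(size=30), 1)  # rounding forces ties
        y = rng.random(30) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        _, auc = roc_auc(conf, y)
        pos, neg = conf[y], conf[~y]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        conf = rng.normal(size=50)
        y = rng.random(50) < 0.4
        _, auc = roc_auc(conf, y)
        assert auc == pytest.approx(roc_auc_score(y, conf), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        conf = rng.normal(size=40)
        y = rng.random(40) < 0.5
        _, a = roc_auc(conf, y)
        _, b = roc_auc(np.exp(2.0 * conf) + 7.0, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestForwardSelection:
    def _panel(self, n=40, n_noise=20, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.Series(["case"] * (n // 2) + ["control"] * (n // 2),
                      index=[f"S{i:03d}" for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, n_noise)),
                         index=y.index,
                         columns=[str(2000 + 10 * j) for j in range(n_noise)])
        X["1000"] = np.where(y == "case", 5.0, -5.0) + rng.normal(0, 0.1, n)
        return X, y

    def test_perfectly_separating_feature_selected_alone(self):
        X, y = self._panel()
        model = forward_select_svm(X, y, "case", k=10, seed=0)
        assert model.selected_features == ["1000"]
        assert model.cv_performance == [1.0]

    def test_max_features_cap_honored(self):
        rng = np.random.default_rng(1)
        n = 60
        y = pd.Series(["case"] * 30 + ["control"] * 30,
                      index=[f"S{i:03d}" for i in range(n)])
        shift = np.where(y == "case", 0.35, 0.0)
        X = pd.DataFrame(
            {str(1000 + j): rng.normal(shift, 1.0) for j in range(30)},
            index=y.index)
        model = forward_select_svm(X, y, "case", k=5, max_features=20, seed=1)
        assert len(model.selected_features) <= 20

    def test_planted_features_recovered(self):
        """Both planted fold-3 ions selected on a synthetic cohort."""
        hits = 0
        for seed in range(3):
            cfg = SimulationConfig(
                n_cases=60, n_controls=60, n_common_peaks=102,
                planted_discriminant_peaks=((2000.0, 3.0, "up"), (5000.0, 3.0, "up")),
                seed=seed)
            fm, gt = simulate_feature_matrix(cfg)
            labels = fm.metadata["group"].map(
                lambda g: "case" if g == "ccRCC" else "control")
            model = forward_select_svm(fm.areas, labels, "case", k=10, seed=seed)
            planted = {fm.areas.columns[np.argmin(np.abs(gt.peak_mz - mz))]
                       for mz in gt.discriminant_mz}
            hits += planted <= set(model.selected_features)
        assert hits >= 2

    def test_too_few_subjects_per_class_rejected(self):
        X, y = self._panel(n=10)
        with pytest.raises(ValueError, match="stratified"):
            forward_select_svm(X, y, "case", k=10)

    def test_model_json_round_trip(self, tmp_path):
        X, y = self._panel()
        model = forward_select_svm(X, y, "case", k=5, seed=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClassifierModel.from_json(path)
        np.testing.assert_allclose(back.coef, model.coef)
        assert back.selected_features == model.selected_features
        np.testing.assert_allclose(back.decision_values(X), model.decision_values(X))


class TestEvaluate:
    def test_evaluation_on_held_out_panel(self):
        X, y = self._make()
        model = forward_select_svm(X.iloc[:30], y.iloc[:30], "case", k=5, seed=0)
        report = evaluate(model, X.iloc[30:], y.iloc[30:])
        cm = report.confusion
        assert cm.tp + cm.fp + cm.tn + cm.fn == 10
        assert report.auc == 1.0  # separable construction
        assert report.metrics()["sensitivity_pct"] == 100.0

    def test_missing_feature_column_rejected(self):
        X, y = self._make()
        model = forward_select_svm(X, y, "case", k=5, seed=0)
        with pytest.raises(KeyError, match="missing"):
            model.decision_values(X.drop(columns=model.selected_features))

    def test_cross_validated_report_counts(self):
        X, y = self._make()
        report = cross_validated_report(X, y, ["1000"], "case", k=5, seed=0)
        assert report.n_subjects == len(y)
        cm = report.confusion
        assert cm.tp + cm.fn == (y == "case").sum()

    @staticmethod
    def _make(n=40, seed=6):
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        y = pd.Series(np.where(order % 2 == 0, "case", "control"),
                      index=[f"S{i:03d}" for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         index=y.index, columns=[str(j) for j in range(5)])
        X["1000"] = np.where(y == "case", 4.0, -4.0) + rng.normal(0, 0.2, n)
        return X, y
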