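from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import gaussian_feature_table
from ergosc.classify import (
    RFGrid,
    balance_classes,
    build_feature_table,
    evaluate,
    feature_columns,
    hierarchical_multiclass,
    metrics_from_confusion,
    roc_points,
    split_train_test,
    trapezoid_auc,
    tune_fit_rf,
    week_multiclass,
)
from ergosc.spectral import Band, PowerSpectrum, frequency_grid


def mann_whitney_auc(y, scores):
    """Brute-force pairwise probability that a positive outranks a negative."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


class TestBuildFeatureTable:
    def _spectra(self, n, fmin=0.3, fmax=40.0):
        freqs = frequency_grid(fmin, fmax, 0.05)
        rng = np.random.default_rng(0)
        return [PowerSpectrum(freqs=freqs, power=rng.random(freqs.size)) for _ in range(n)]

    def test_human_grid_gives_795_power_columns(self):
        table = build_feature_table(self._spectra(2), ["f0", "f1"], ["s0", "s0"],
                                    ["control", "control"])
        assert len([c for c in table.columns if c.startswith("p_")]) == 795

    def test_band_feature_columns(self):
        bands = (Band("I", 0.3, 2.0), Band("III", 20.0, 40.0))
        table = build_feature_table(self._spectra(1), ["f0"], ["s0"], ["x"], bands=bands)
        assert {"auc_I", "pf_I", "auc_III", "pf_III"} <= set(table.columns)

    def test_shared_subject(self):
        table = build_feature_table(self._spectra(2), ["f0", "f1"], ["s0", "s0"], ["a", "a"])
        assert (table["subject_id"] == "s0").all()

    def test_unlabeled_fragment_named_in_error(self):
        with pytest.raises(ValueError, match="f1"):
            build_feature_table(self._spectra(2), ["f0", "f1"], ["s0", "s1"], ["a", None])

    def test_grid_mismatch_rejected(self):
        specs = self._spectra(1) + self._spectra(1, fmax=30.0)
        with pytest.raises(ValueError):
            build_feature_table(specs, ["f0", "f1"], ["s0", "s1"], ["a", "b"])


class TestBalanceSplit:
    def test_undersampling_counts(self):
        df = gaussian_feature_table(100, {"A": 0.0})
        df2 = gaussian_feature_table(40, {"B": 0.0}, seed=1)
        table = pd.concat([df, df2], ignore_index=True)
        out = balance_classes(table, seed=0)
        assert out["label"].value_counts().to_dict() == {"A": 40, "B": 40}

    def test_balanced_input_unchanged_cardinality(self):
        table = gaussian_feature_table(30, {"A": 0.0, "B": 1.0})
        assert len(balance_classes(table, seed=0)) == 60

    def test_balance_deterministic(self):
        table = gaussian_feature_table(50, {"A": 0.0, "B": 1.0})
        a = balance_classes(table.iloc[:80], seed=5)
        b = balance_classes(table.iloc[:80], seed=5)
        assert a.index.equals(b.index)

    def test_split_80_20(self):
        table = gaussian_feature_table(50, {"A": 0.0, "B": 0.0})
        train, test = split_train_test(table, 0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert set(train.index).isdisjoint(test.index)

    def test_subject_mode_keeps_subjects_together(self):
        table = gaussian_feature_table(25, {"A": 0.0, "B": 0.0}, frags_per_subject=5)
        train, test = split_train_test(table, 0.8, unit="subject", seed=0)
        assert set(train["subject_id"]).isdisjoint(test["subject_id"])
        counts = pd.concat([train, test]).groupby("subject_id").size()
        assert (counts == 5).all()

    def test_split_deterministic(self):
        table = gaussian_feature_table(20, {"A": 0.0, "B": 0.0})
        a, _ = split_train_test(table, 0.8, seed=3)
        b, _ = split_train_test(table, 0.8, seed=3)
        assert a.index.equals(b.index)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(gaussian_feature_table(10, {"A": 0.0}), 1.5)


class TestTuneFitRF:
    def test_separable_training_auc_is_one(self):
        table = gaussian_feature_table(30, {"neg": 0.0, "pos": 10.0})
        fitted = tune_fit_rf(table, RFGrid.small(), seed=0)
        X = table[feature_columns(table)].to_numpy()
        p = fitted.model.predict_proba(X)[:, 1]
        roc = roc_points((table["label"] == "pos").astype(int).to_numpy(), p, 1)
        assert trapezoid_auc(roc) == pytest.approx(1.0)

    def test_single_cell_grid_is_chosen(self):
        table = gaussian_feature_table(20, {"a": 0.0, "b": 2.0})
        grid = RFGrid(ntrees=(70,), max_depth=(9,), min_rows=(3,))
        fitted = tune_fit_rf(table, grid, seed=0)
        assert fitted.params == {"ntrees": 70, "max_depth": 9, "min_rows": 3}

    def test_permuted_labels_give_chance_cv_auc(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            table = gaussian_feature_table(40, {"a": 0.0, "b": 0.0}, seed=seed)
            table["label"] = rng.permutation(table["label"].to_numpy())
            fitted = tune_fit_rf(table, RFGrid(ntrees=(50,), max_depth=(9,), min_rows=(2,)),
                                 seed=seed)
            aucs.append(fitted.cv_score)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tune_fit_rf(gaussian_feature_table(20, {"a": 0.0}), RFGrid.small())


class TestEvaluate:
    def test_confusion_metric_arithmetic(self):
        m = metrics_from_confusion(tp=8, fn=2, fp=3, tn=7)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(8 / 11)
        assert m["npv"] == pytest.approx(7 / 9)
        assert m["f1"] == pytest.approx(2 * (8 / 11) * 0.8 / ((8 / 11) + 0.8))

    def test_perfect_probabilities_auc_one(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        p = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert trapezoid_auc(roc_points(y, p, 1)) == pytest.approx(1.0)

    def test_roc_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        roc = roc_points(y, p, 1)
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()

    def test_report_consistent_with_confusion(self):
        table = gaussian_feature_table(30, {"neg": 0.0, "pos": 3.0})
        train, test = split_train_test(table, 0.8, seed=1)
        fitted = tune_fit_rf(train, RFGrid.small(), seed=1)
        rep = evaluate(fitted, test, positive_class="pos")
        tp, fn = rep.confusion[0]
        fp, tn = rep.confusion[1]
        assert tp + fn + fp + tn == len(test)
        m = metrics_from_confusion(tp, fn, fp, tn)
        assert rep.accuracy == pytest.approx(m["accuracy"])
        assert rep.f1 == pytest.approx(m["f1"])

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_metric_identities_hold_for_any_confusion(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        m = metrics_from_confusion(tp, fn, fp, tn)
        assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fn + fp + tn))
        if tp + fn:
            assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m["specificity"] == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert m["precision"] == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert m["npv"] == pytest.approx(tn / (tn + fn))


class TestAUCOracle:
    def test_trapezoid_auc_equals_mann_whitney_exhaustive(self):
        """Exhaustive agreement with the pairwise-comparison oracle, n <= 12."""
        rng = np.random.default_rng(0)
        for n in range(2, 11):
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            for pattern in product([0, 1], repeat=n):
                y = np.array(pattern)
                if y.min() == y.max():
                    continue
                auc = trapezoid_auc(roc_points(y, scores, 1))
                assert auc == pytest.approx(mann_whitney_auc(y, scores), abs=1e-12)

    def test_oracle_agreement_at_n20(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            y = rng.integers(0, 2, 20)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(20), 1)
            auc = trapezoid_auc(roc_points(y, scores, 1))
            assert auc == pytest.approx(mann_whitney_auc(y, scores), abs=1e-12)


class TestMulticlass:
    def test_hierarchical_separable_groups(self):
        shifts = {"control": 0.0, "overweight": 3.0, "obesity": 6.0,
                  "mets": 9.0, "dm_no_dr": 12.0}
        table = gaussian_feature_table(30, shifts, seed=4)
        train, test = split_train_test(table, 0.8, seed=4)
        rep = hierarchical_multiclass(train, test, RFGrid.small(), seed=4)
        assert rep.confusion.sum() == len(test)
        assert rep.accuracy > 0.2  # above 5-class chance
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / len(test))

    def test_hierarchical_requires_control_and_subclasses(self):
        table = gaussian_feature_table(20, {"control": 0.0, "mets": 1.0})
        train, test = split_train_test(table, 0.8, seed=0)
        with pytest.raises(ValueError):
            hierarchical_multiclass(train, test, RFGrid.small())

    def test_week_classes_with_progressive_shift(self):
        tables = {
            wk: gaussian_feature_table(25, {"x": 2.0 * i}, seed=wk)
            for i, wk in enumerate([4, 6, 8, 12])
        }
        rep = week_multiclass(tables, RFGrid.small(), seed=0)
        assert rep.accuracy > 0.25
        assert rep.labels == ("12", "4", "6", "8")

    def test_identical_timepoints_near_chance(self):
        tables = {wk: gaussian_feature_table(40, {"x": 0.0}, seed=wk) for wk in (4, 6)}
        rep = week_multiclass(tables, RFGrid(ntrees=(50,), max_depth=(9,), min_rows=(2,)),
                              seed=1)
        off_diag = rep.confusion.sum() - np.trace(rep.confusion)
        assert 0.2 <= off_diag / rep.confusion.sum() <= 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            week_multiclass({4: gaussian_feature_table(10, {"x": 0.0})})
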