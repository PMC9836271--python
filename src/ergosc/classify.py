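"""Random-forest screening models and their performance metrics.

Feature tables hold one row per one-minute fragment: the normalized wavelet
power at every 0.05 Hz grid frequency of the analysis band, plus band AUC and
band peak-frequency features, a group label, and provenance columns.  Models
are random forests tuned by exhaustive grid search over
(ntrees, max_depth, min_rows) with stratified cross-validation; classes are
balanced by seeded undersampling before splitting, and an 80/20 train/test
split is the default.  Evaluation produces the ROC curve from sorted class
probabilities, trapezoidal AUC, the 0.5-threshold confusion matrix, and the
six scalar metrics (accuracy, sensitivity, specificity, precision, NPV, F1).

Splitting at fragment level reproduces the published protocol but permits a
subject's fragments to straddle the split; ``unit="subject"`` keeps each
subject on one side and is recommended for leakage-free estimates.  Reports
record which was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .spectral import Band, PowerSpectrum, band_auc, band_peak_frequency

__all__ = [
    "ID_COLUMNS",
    "RFGrid",
    "FittedModel",
    "ClassifierReport",
    "MulticlassReport",
    "build_feature_table",
    "feature_columns",
    "balance_classes",
    "split_train_test",
    "tune_fit_rf",
    "evaluate",
    "hierarchical_multiclass",
    "week_multiclass",
    "roc_points",
    "trapezoid_auc",
    "metrics_from_confusion",
]

ID_COLUMNS = ("fragment_id", "subject_id", "label")


@dataclass(frozen=True)
class RFGrid:
    """Hyperparameter grid: tree count, depth, minimum rows per leaf."""

    ntrees: tuple[int, ...] = (100,)
    max_depth: tuple[int, ...] = (15,)
    min_rows: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if any(v < 1 for v in (*self.ntrees, *self.max_depth, *self.min_rows)):
            raise ValueError("all grid entries must be >= 1")

    @classmethod
    def paper(cls) -> "RFGrid":
        """The full published tuning grid (528 cells)."""
        return cls(
            ntrees=(50, 70, 90, 100, 150, 200, 250, 300, 350, 400, 450, 500),
            max_depth=(9, 10, 11, 12, 13, 14, 15, 16, 17, 19, 20),
            min_rows=(1, 2, 3, 4),
        )

    @classmethod
    def small(cls) -> "RFGrid":
        """A desk-scale grid for tests and simulation studies."""
        return cls(ntrees=(100,), max_depth=(15,), min_rows=(1, 2))

    def cells(self):
        return sorted(product(self.ntrees, self.max_depth, self.min_rows))


@dataclass
class FittedModel:
    model: RandomForestClassifier
    params: dict
    cv_score: float
    classes: list
    criterion: str  # "auc" or "accuracy"


@dataclass
class ClassifierReport:
    """Binary-evaluation bundle: ROC, AUC, confusion matrix, scalar metrics."""

    roc: np.ndarray  # (k, 2) of (FPR, TPR)
    auc: float | None
    confusion: np.ndarray  # rows actual, cols predicted, order [pos, neg]
    positive_class: str
    labels: tuple
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    f1: float
    config: dict = _field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "roc": np.asarray(self.roc).tolist(),
            "auc": self.auc,
            "confusion": np.asarray(self.confusion).tolist(),
            "positive_class": self.positive_class,
            "labels": list(self.labels),
            "metrics": {
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "npv": self.npv, "f1": self.f1,
            },
            "config": self.config,
        }


@dataclass
class MulticlassReport:
    labels: tuple
    confusion: np.ndarray  # rows actual, cols predicted
    accuracy: float
    config: dict = _field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": np.asarray(self.confusion).tolist(),
            "accuracy": self.accuracy,
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# feature assembly

def build_feature_table(
    spectra: Sequence[PowerSpectrum],
    fragment_ids: Sequence[str],
    subject_ids: Sequence[str],
    labels: Sequence[str | None],
    bands: Sequence[Band] = (),
) -> pd.DataFrame:
    """Assemble the per-fragment feature table.

    Columns: ``p_<freq>`` for every grid frequency, then ``auc_<band>`` and
    ``pf_<band>`` per requested band, then the ID columns.  All spectra must
    share one grid and every fragment must be labeled.
    """
    if not (len(spectra) == len(fragment_ids) == len(subject_ids) == len(labels)):
        raise ValueError("spectra, ids and labels must have equal lengths")
    if not spectra:
        raise ValueError("no spectra given")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != f0.shape or not np.allclose(s.freqs, f0):
            raise ValueError("mismatched frequency grids across fragments")
    for fid, lab in zip(fragment_ids, labels):
        if lab is None:
            raise ValueError(f"fragment {fid!r} has no label")
    power_cols = [f"p_{f:.2f}" for f in f0]
    rows = np.vstack([s.power for s in spectra])
    df = pd.DataFrame(rows, columns=power_cols)
    for band in bands:
        df[f"auc_{band.label}"] = [band_auc(s, band) for s in spectra]
        df[f"pf_{band.label}"] = [band_peak_frequency(s, band) for s in spectra]
    df["fragment_id"] = list(fragment_ids)
    df["subject_id"] = list(subject_ids)
    df["label"] = list(labels)
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def balance_classes(table: pd.DataFrame, seed=0) -> pd.DataFrame:
    """Equalize class counts by seeded random undersampling of majorities."""
    counts = table["label"].value_counts()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError("need at least two non-empty classes to balance")
    n_min = int(counts.min())
    rng = np.random.default_rng(_seed_int(seed))
    keep = []
    for lab in sorted(counts.index):
        idx = table.index[table["label"] == lab].to_numpy()
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return table.loc[keep]


def split_train_test(
    table: pd.DataFrame,
    train_frac: float = 0.8,
    unit: str = "fragment",
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/test partition at fragment or subject level."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(_seed_int(seed))
    if unit == "fragment":
        perm = rng.permutation(len(table))
        n_train = int(round(len(table) * train_frac))
        if n_train == 0 or n_train == len(table):
            raise ValueError("not enough rows for both partitions")
        return table.iloc[np.sort(perm[:n_train])], table.iloc[np.sort(perm[n_train:])]
    if unit == "subject":
        subjects = np.array(sorted(table["subject_id"].unique()))
        perm = rng.permutation(len(subjects))
        n_train = int(round(len(subjects) * train_frac))
        if n_train == 0 or n_train == len(subjects):
            raise ValueError("not enough subjects for both partitions")
        train_subj = set(subjects[perm[:n_train]])
        mask = table["subject_id"].isin(train_subj).to_numpy()
        return table.loc[mask], table.loc[~mask]
    raise ValueError("unit must be 'fragment' or 'subject'")


# ---------------------------------------------------------------------------
# model fitting and evaluation

def tune_fit_rf(
    train: pd.DataFrame,
    grid: RFGrid | None = None,
    cv_folds: int = 5,
    seed=0,
) -> FittedModel:
    """Exhaustive grid search with stratified CV, then refit on all of train.

    Binary problems select by mean cross-validated AUC, multiclass by
    accuracy; ties break toward the smallest ntrees, then max_depth, then
    min_rows (the sorted cell order).
    """
    grid = grid or RFGrid.small()
    X = train[feature_columns(train)].to_numpy(float)
    y = train["label"].to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training set has a single class")
    counts = pd.Series(y).value_counts()
    if counts.min() < cv_folds:
        raise ValueError(f"need >= {cv_folds} rows per class for {cv_folds}-fold CV")
    criterion = "auc" if len(classes) == 2 else "accuracy"
    base_seed = _seed_int(seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=base_seed % (2**31))
    best = None
    for cell_i, (ntrees, depth, min_rows) in enumerate(grid.cells()):
        scores = []
        for tr_idx, va_idx in skf.split(X, y):
            rf = _make_rf(ntrees, depth, min_rows, base_seed)
            rf.fit(X[tr_idx], y[tr_idx])
            if criterion == "auc":
                p = rf.predict_proba(X[va_idx])[:, list(rf.classes_).index(classes[1])]
                yb = (y[va_idx] == classes[1]).astype(int)
                scores.append(roc_auc_score(yb, p))
            else:
                scores.append(float(np.mean(rf.predict(X[va_idx]) == y[va_idx])))
        mean_score = float(np.mean(scores))
        if best is None or mean_score > best[0]:
            best = (mean_score, ntrees, depth, min_rows)
    score, ntrees, depth, min_rows = best
    model = _make_rf(ntrees, depth, min_rows, base_seed)
    model.fit(X, y)
    return FittedModel(
        model=model,
        params={"ntrees": ntrees, "max_depth": depth, "min_rows": min_rows},
        cv_score=score, classes=classes, criterion=criterion,
    )


def _make_rf(ntrees, depth, min_rows, seed) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntrees, max_depth=depth, min_samples_leaf=min_rows,
        random_state=seed % (2**31), n_jobs=1,
    )


def roc_points(y_true: np.ndarray, scores: np.ndarray, pos_label) -> np.ndarray:
    """ROC curve (FPR, TPR) from sorted class probabilities; full resolution."""
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=pos_label, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def trapezoid_auc(roc: np.ndarray) -> float:
    roc = np.asarray(roc)
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict:
    """The six scalar metrics; undefined ratios come back as NaN."""

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else float("nan"))
    return {
        "accuracy": ratio(tp + tn, tp + fn + fp + tn),
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "precision": prec,
        "npv": ratio(tn, tn + fn),
        "f1": f1,
    }


def evaluate(
    fitted: FittedModel,
    test: pd.DataFrame,
    positive_class: str,
    threshold: float = 0.5,
    config: Mapping | None = None,
) -> ClassifierReport:
    """Score a fitted binary model on a held-out table.

    ROC and trapezoidal AUC come from the positive-class probabilities; the
    confusion matrix and scalar metrics use the ``threshold`` (default 0.5)
    decision rule.  A single-class test set yields metrics where defined and
    an undefined (None) AUC.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    model = fitted.model
    if positive_class not in model.classes_:
        raise ValueError(f"positive class {positive_class!r} unknown to the model")
    X = test[feature_columns(test)].to_numpy(float)
    y = test["label"].to_numpy()
    p = model.predict_proba(X)[:, list(model.classes_).index(positive_class)]
    actual_pos = y == positive_class
    pred_pos = p >= threshold
    tp = int(np.sum(actual_pos & pred_pos))
    fn = int(np.sum(actual_pos & ~pred_pos))
    fp = int(np.sum(~actual_pos & pred_pos))
    tn = int(np.sum(~actual_pos & ~pred_pos))
    metrics = metrics_from_confusion(tp, fn, fp, tn)
    if actual_pos.all() or (~actual_pos).all():
        warnings.warn("single-class test set: AUC undefined", stacklevel=2)
        roc, auc = np.empty((0, 2)), None
    else:
        roc = roc_points(actual_pos.astype(int), p, 1)
        auc = trapezoid_auc(roc)
    neg = "~" + positive_class
    return ClassifierReport(
        roc=roc, auc=auc,
        confusion=np.array([[tp, fn], [fp, tn]]),
        positive_class=positive_class, labels=(positive_class, neg),
        config=dict(config or {}), **metrics,
    )


def hierarchical_multiclass(
    train: pd.DataFrame,
    test: pd.DataFrame,
    grid: RFGrid | None = None,
    seed=0,
    control_label: str = "control",
    cv_folds: int = 5,
) -> MulticlassReport:
    """Two-stage five-class prediction: control-vs-disease, then subclass.

    Stage 1 is a binary forest; test rows it calls diseased go to a stage-2
    forest trained on the disease subclasses only.  Control calls from stage 1
    are final.  The confusion matrix has actual labels as rows and predicted
    as columns over all five classes.
    """
    labels = tuple(sorted(set(train["label"])))
    disease = [g for g in labels if g != control_label]
    if control_label not in labels or len(disease) < 2:
        raise ValueError("train must contain the control label and >= 2 disease classes")
    s1, s2, s3 = _child_seeds(seed, 3)
    stage1_train = train.copy()
    stage1_train["label"] = np.where(train["label"] == control_label, control_label, "disease")
    fitted1 = tune_fit_rf(stage1_train, grid, cv_folds=cv_folds, seed=s1)
    fitted2 = tune_fit_rf(train[train["label"] != control_label], grid, cv_folds=cv_folds, seed=s2)
    X = test[feature_columns(test)].to_numpy(float)
    p_dis = fitted1.model.predict_proba(X)[:, list(fitted1.model.classes_).index("disease")]
    pred = np.where(p_dis >= 0.5, "", control_label).astype(object)
    dis_mask = pred == ""
    if dis_mask.any():
        pred[dis_mask] = fitted2.model.predict(X[dis_mask])
    actual = test["label"].to_numpy()
    conf = _confusion(actual, pred, labels)
    return MulticlassReport(
        labels=labels, confusion=conf,
        accuracy=float(np.mean(pred == actual)),
        config={"stage1": fitted1.params, "stage2": fitted2.params, "seed": _seed_int(seed)},
    )


def week_multiclass(
    tables: Mapping[int | str, pd.DataFrame],
    grid: RFGrid | None = None,
    seed=0,
    train_frac: float = 0.8,
    cv_folds: int = 5,
) -> MulticlassReport:
    """Single multiclass forest over timepoint (week) classes.

    Tables are relabeled by their key, pooled, balanced, split 80/20, tuned
    and fitted; the confusion matrix has actual weeks as rows and predicted
    weeks as columns.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 timepoint classes")
    parts = []
    for key, df in tables.items():
        part = df.copy()
        part["label"] = str(key)
        parts.append(part)
    pooled = pd.concat(parts, ignore_index=True)
    s1, s2, s3 = _child_seeds(seed, 3)
    pooled = balance_classes(pooled, seed=s1)
    train, test = split_train_test(pooled, train_frac=train_frac, unit="fragment", seed=s2)
    fitted = tune_fit_rf(train, grid, cv_folds=cv_folds, seed=s3)
    pred = fitted.model.predict(test[feature_columns(test)].to_numpy(float))
    actual = test["label"].to_numpy()
    labels = tuple(sorted(set(pooled["label"])))
    return MulticlassReport(
        labels=labels, confusion=_confusion(actual, pred, labels),
        accuracy=float(np.mean(pred == actual)),
        config={"params": fitted.params, "seed": _seed_int(seed)},
    )


def _confusion(actual, pred, labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, pred):
        conf[index[a], index[p]] += 1
    return conf


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0])
    return int(seed)


def _child_seeds(seed, n: int) -> list[int]:
    ss = np.random.SeedSequence(_seed_int(seed))
    return [int(s) for s in ss.generate_state(n)]
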