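"""Explanatory statistics: CoV variable selection, PCA, the SO score, LDA,
Pearson correlation, and Welch's heteroscedastic ANOVA.

These mirror the explanatory layer used around the screening model: variables
with the highest coefficient of variation are selected, PCA (on standardized
variables by default, since spectral power and plasma analytes mix scales)
summarizes their structure with per-variable contributions, a spontaneous-
oscillation (SO) score linearly combines the PC1 loadings with each subject's
values, linear discriminant analysis separates user-defined groups, and
Welch's ANOVA compares cohort characteristics without assuming equal
variances.  Games-Howell pairwise comparisons (via pingouin) back the
compact-letter group annotations of cohort tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "PCAResult",
    "LDAResult",
    "WelchResult",
    "select_high_cov",
    "run_pca",
    "so_score",
    "pearson_correlation",
    "run_lda",
    "coarse_disease_groups",
    "welch_anova",
    "games_howell",
    "compact_letters",
]


@dataclass
class PCAResult:
    variables: list[str]
    loadings: np.ndarray  # (n_vars, n_comp), orthonormal columns
    scores: np.ndarray  # (n_cases, n_comp)
    variance_fraction: np.ndarray
    contributions: np.ndarray  # squared loading / column sum, per component
    mean: np.ndarray
    scale: np.ndarray  # ones when unstandardized
    index: pd.Index  # complete-case row index


@dataclass
class LDAResult:
    groups: list[str]
    axes: np.ndarray  # (n_vars, <= n_groups - 1)
    group_means: pd.DataFrame
    confusion: np.ndarray  # rows actual, cols predicted
    recall: dict[str, float]
    validation: str


@dataclass
class WelchResult:
    F: float
    df1: float
    df2: float
    p: float


def select_high_cov(
    table: pd.DataFrame, k: int, variables: Sequence[str] | None = None
) -> list[str]:
    """Top-``k`` numeric variables by coefficient of variation (sd/|mean|).

    Zero-mean variables are excluded with a warning; ties break by name.
    """
    cols = list(variables) if variables is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    scored = []
    for c in cols:
        x = table[c].dropna().to_numpy(float)
        mean = x.mean()
        if mean == 0:
            warnings.warn(f"variable {c!r} has zero mean; CoV undefined, excluded",
                          stacklevel=2)
            continue
        scored.append((x.std(ddof=1) / abs(mean), c))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [c for _, c in scored[:k]]


def run_pca(
    table: pd.DataFrame, variables: Sequence[str], standardize: bool = True
) -> PCAResult:
    """PCA of the complete cases of the selected variables.

    Eigen-decomposition (via SVD) of the covariance of centered — and by
    default standardized — variables.  Contributions are squared loadings
    normalized per component.
    """
    sub = table[list(variables)].dropna()
    if len(sub) < 2:
        raise ValueError("need at least two complete cases")
    X = sub.to_numpy(float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1) if standardize else np.ones(X.shape[1])
    if np.any(scale == 0):
        bad = [v for v, s in zip(variables, scale) if s == 0]
        raise ValueError(f"constant variables cannot be standardized: {bad}")
    Z = (X - mean) / scale
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    scores = Z @ loadings
    var = s**2
    contributions = loadings**2
    contributions = contributions / contributions.sum(axis=0, keepdims=True)
    return PCAResult(
        variables=list(variables), loadings=loadings, scores=scores,
        variance_fraction=var / var.sum(), contributions=contributions,
        mean=mean, scale=scale, index=sub.index,
    )


def so_score(
    table: pd.DataFrame,
    loadings: Mapping[str, float],
    center: Mapping[str, float] | None = None,
    scale: Mapping[str, float] | None = None,
) -> pd.Series:
    """Spontaneous-oscillation score: sum of PC1 loading x variable value.

    With ``center``/``scale`` given, values are standardized first (the
    consistent choice when the PCA ran on standardized data); otherwise raw
    values are used.  Variable names must match the table exactly.
    """
    names = list(loadings)
    missing = [v for v in names if v not in table.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    X = table[names].to_numpy(float)
    if center is not None:
        X = X - np.array([center[v] for v in names])
    if scale is not None:
        X = X / np.array([scale[v] for v in names])
    w = np.array([loadings[v] for v in names])
    return pd.Series(X @ w, index=table.index, name="so_score")


def so_score_from_pca(table: pd.DataFrame, pca: PCAResult, component: int = 0) -> pd.Series:
    """SO score using a PCA result's PC loadings and its centering/scaling."""
    names = pca.variables
    w = dict(zip(names, pca.loadings[:, component]))
    center = dict(zip(names, pca.mean))
    scale = dict(zip(names, pca.scale))
    return so_score(table, w, center=center, scale=scale)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment r with a two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def run_lda(
    table: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    validation: str = "resubstitution",
) -> LDAResult:
    """Fisher linear discriminant analysis with per-group recall.

    ``validation`` is ``resubstitution`` (fit and score on the same cases) or
    ``loo`` (leave-one-out predictions).  Near-singular within-group
    covariance falls back to a shrinkage solver.
    """
    sub = table[[*variables, group_col]].dropna()
    y = sub[group_col].to_numpy()
    groups = sorted(set(y))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    X = sub[list(variables)].to_numpy(float)
    lda = LinearDiscriminantAnalysis()
    try:
        lda.fit(X, y)
    except np.linalg.LinAlgError:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
    if validation == "resubstitution":
        pred = lda.predict(X)
    elif validation == "loo":
        from sklearn.model_selection import LeaveOneOut, cross_val_predict

        pred = cross_val_predict(lda, X, y, cv=LeaveOneOut())
    else:
        raise ValueError("validation must be 'resubstitution' or 'loo'")
    idx = {g: i for i, g in enumerate(groups)}
    conf = np.zeros((len(groups), len(groups)), dtype=int)
    for a, p in zip(y, pred):
        conf[idx[a], idx[p]] += 1
    recall = {
        g: conf[i, i] / conf[i].sum() if conf[i].sum() else float("nan")
        for i, g in enumerate(groups)
    }
    axes = getattr(lda, "scalings_", np.zeros((X.shape[1], 0)))[:, : len(groups) - 1]
    means = pd.DataFrame(lda.means_, index=groups, columns=list(variables))
    return LDAResult(
        groups=groups, axes=axes, group_means=means,
        confusion=conf, recall=recall, validation=validation,
    )


def coarse_disease_groups(labels: Sequence[str]) -> list[str]:
    """Map the five study groups to control / risk_factors / diabetes."""
    out = []
    for lab in labels:
        if lab == "control":
            out.append("control")
        elif lab in ("overweight", "obesity", "mets"):
            out.append("risk_factors")
        elif lab == "dm_no_dr":
            out.append("diabetes")
        else:
            raise ValueError(f"unknown group label {lab!r}")
    return out


def welch_anova(groups: Sequence[np.ndarray]) -> WelchResult:
    """Welch's heteroscedastic one-way F test with Satterthwaite df."""
    arrays = [np.asarray(g, float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([a.size for a in arrays], float)
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    var = np.array([a.var(ddof=1) for a in arrays])
    if np.any(var == 0):
        raise ValueError("a group has zero variance")
    means = np.array([a.mean() for a in arrays])
    w = n / var
    W = w.sum()
    grand = (w * means).sum() / W
    A = (w * (means - grand) ** 2).sum() / (k - 1)
    r = ((1 - w / W) ** 2 / (n - 1)).sum()
    B = 1 + 2.0 * (k - 2) / (k**2 - 1) * r
    F = A / B
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3.0 * r)
    p = float(_stats.f.sf(F, df1, df2))
    return WelchResult(F=float(F), df1=df1, df2=df2, p=p)


def games_howell(samples: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (pingouin backend)."""
    import pingouin as pg

    data = pd.DataFrame(
        [(g, v) for g, arr in samples.items() for v in np.asarray(arr, float)],
        columns=["group", "value"],
    )
    return pg.pairwise_gameshowell(dv="value", between="group", data=data)


def compact_letters(groups: Sequence[str], significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different (insert-and-absorb over the non-significance graph)."""
    groups = list(groups)
    sig = {frozenset(p) for p in significant_pairs}
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) not in sig for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb duplicates
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out
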