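"""Group discrimination from repeatable radiomic features.

Implements the downstream classification analysis: restrict to features
repeatable under scan–rescan variability, drop zero-variance and
volume-redundant columns, select five features by bootstrapped
minimum-redundancy-maximum-relevance (MRMR), fit a logistic-regression
classifier under leave-one-patient-out cross-validation, and compare ROC
curves between methods with the DeLong test for correlated AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler

from .errors import InputError, ParameterError

__all__ = [
    "filter_features",
    "mrmr_rank",
    "mrmr_bootstrap",
    "ClassifierReport",
    "fit_eval_lopo",
    "delong_auc_variance",
    "delong_test",
]


def filter_features(
    table: pd.DataFrame, volume_col: str = "shape_MeshVolume", r_max: float = 0.8
) -> pd.DataFrame:
    """Drop zero-variance columns and columns with |Pearson r| > ``r_max``
    against the volume surrogate; the volume column itself is retained."""
    if volume_col not in table.columns:
        raise ParameterError(f"{volume_col} not present in the feature table")
    keep: List[str] = []
    vol = table[volume_col].to_numpy(dtype=float)
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.isnan(x).any() or np.std(x) == 0:
            continue
        if col != volume_col:
            r = np.corrcoef(x, vol)[0, 1]
            if np.abs(r) > r_max:
                continue
        keep.append(col)
    return table[keep]


def _relevance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ANOVA F-statistic of each feature against the class label."""
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_classif(X, y)
    return np.nan_to_num(F, nan=0.0, posinf=0.0)


def mrmr_rank(X: np.ndarray, y: np.ndarray, k: int) -> List[int]:
    """Greedy MRMR (FCQ quotient criterion): start from the most relevant
    feature, then repeatedly add the feature maximizing
    ``F-statistic / mean |Pearson r| with the already-selected set``.

    The quotient form keeps relevance (an unbounded F statistic) and
    redundancy (a correlation in [0, 1]) on comparable footing; the
    redundancy denominator is floored at 0.01 to bound the score, and a
    candidate nearly collinear with an already-selected feature
    (max |r| > 0.95) is deferred until no other candidates remain.
    """
    n_feat = X.shape[1]
    k = min(k, n_feat)
    rel = _relevance(X, y)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    corr_cache: Dict[int, np.ndarray] = {}
    selected = [int(np.argmax(rel))]
    while len(selected) < k:
        red_mean = np.zeros(n_feat)
        red_max = np.zeros(n_feat)
        for s in selected:
            if s not in corr_cache:
                corr_cache[s] = np.abs(Z.T @ Z[:, s]) / X.shape[0]
            red_mean += corr_cache[s]
            red_max = np.maximum(red_max, corr_cache[s])
        red_mean /= len(selected)
        best, best_score = -1, -np.inf
        for collinear_ok in (False, True):
            for j in range(n_feat):
                if j in selected:
                    continue
                if red_max[j] > 0.95 and not collinear_ok:
                    continue
                score = rel[j] / max(red_mean[j], 0.01)
                if score > best_score:
                    best, best_score = j, score
            if best >= 0:
                break
        selected.append(best)
    return selected


def mrmr_bootstrap(
    table: pd.DataFrame,
    labels: Sequence,
    n_boot: int = 500,
    k: int = 5,
    seed: int = 0,
) -> List[str]:
    """Select the k features most frequently ranked by MRMR over
    ``n_boot`` bootstrap resamples of the scans.

    Each resample draws scans with replacement (stratification-free), runs
    the greedy MRMR ranking, and tallies the top-k sets; the final
    selection is the k features with the highest selection frequency, ties
    broken by column order for determinism.
    """
    y = np.asarray(pd.factorize(np.asarray(labels))[0])
    if len(np.unique(y)) != 2:
        raise InputError("mrmr_bootstrap needs exactly two classes")
    if table.shape[1] < k:
        raise InputError(f"need at least {k} candidate features, got {table.shape[1]}")
    X = table.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    freq = np.zeros(X.shape[1])
    n = X.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            continue
        for j in mrmr_rank(X[idx], yb, k):
            freq[j] += 1.0
    order = np.lexsort((np.arange(len(freq)), -freq))
    return [table.columns[j] for j in order[:k]]


@dataclass
class ClassifierReport:
    """Pooled out-of-fold predictions and ROC summary of one method."""

    selected_features: List[str]
    y_true: np.ndarray
    y_prob: np.ndarray
    patient_ids: np.ndarray
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    skipped_folds: List[str] = field(default_factory=list)


def fit_eval_lopo(
    table: pd.DataFrame,
    labels: Sequence,
    patient_ids: Sequence,
    selected: Sequence[str],
) -> ClassifierReport:
    """Leave-one-patient-out logistic regression on the selected features.

    Every fold holds out all scans of one patient; features are
    standardized with training-fold statistics only; the model is an
    unpenalized logistic fit, falling back to a light ridge penalty if the
    unpenalized fit fails to converge (complete separation).  ROC and AUC
    are computed over the scan-level out-of-fold predictions pooled across
    folds.
    """
    missing = [f for f in selected if f not in table.columns]
    if missing:
        raise InputError(f"selected features absent from table: {missing}")
    X = table[list(selected)].to_numpy(dtype=float)
    y, classes = pd.factorize(np.asarray(labels))
    if len(classes) != 2:
        raise InputError("need exactly two classes")
    pid = np.asarray(patient_ids)
    probs = np.full(len(y), np.nan)
    skipped: List[str] = []
    for patient in pd.unique(pid):
        test = pid == patient
        train = ~test
        if len(np.unique(y[train])) < 2:
            skipped.append(str(patient))
            continue
        scaler = StandardScaler().fit(X[train])
        Xtr = scaler.transform(X[train])
        Xte = scaler.transform(X[test])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            clf = LogisticRegression(C=np.inf, max_iter=500).fit(Xtr, y[train])
            diverged = (
                not np.all(np.isfinite(clf.coef_)) or int(np.max(clf.n_iter_)) >= 500
            )
            if diverged:  # complete separation: light ridge penalty
                clf = LogisticRegression(C=100.0, max_iter=2000).fit(Xtr, y[train])
        probs[test] = clf.predict_proba(Xte)[:, 1]
    ok = ~np.isnan(probs)
    fpr, tpr, _ = roc_curve(y[ok], probs[ok])
    return ClassifierReport(
        selected_features=list(selected),
        y_true=y[ok],
        y_prob=probs[ok],
        patient_ids=pid[ok],
        auc=float(roc_auc_score(y[ok], probs[ok])),
        fpr=fpr,
        tpr=tpr,
        skipped_folds=skipped,
    )


# --------------------------------------------------------------------------
# DeLong test for correlated ROC curves

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values (structural components) and AUC of one classifier."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # per-positive placement
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # per-negative placement
    return auc, v10, v01


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """(AUC, variance of the AUC estimate) for one classifier."""
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(np.asarray(scores, float), labels)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    return float(auc), float(var)


def delong_test(
    pred_a: Sequence[float], pred_b: Sequence[float], labels: Sequence
) -> float:
    """Two-sided DeLong test comparing two correlated ROC AUCs computed on
    the same scans; returns the p-value (1.0 for identical predictions)."""
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    y = np.asarray(pd.factorize(np.asarray(labels))[0]) if not np.issubdtype(
        np.asarray(labels).dtype, np.number
    ) else np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != y.shape:
        raise InputError("prediction vectors and labels must be aligned")
    if len(np.unique(y)) != 2:
        raise InputError("DeLong test undefined without both classes")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))
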