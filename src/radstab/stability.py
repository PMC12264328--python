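"""Feature-stability analysis via intraclass correlation.

Two reliability questions are asked of every radiomic feature:

* **Reproducibility** with respect to segmentation variability (ICC_S):
  two-way *mixed*-effects, *consistency*, average-measure ICC — ICC(3,k) —
  between feature values from the manual ground-truth masks and from the
  automatic (confidence-level) masks, over the scans of one subject group.
* **Repeatability** with respect to scan–rescan variability (ICC_A):
  two-way *random*-effects, *absolute-agreement*, average-measure ICC —
  ICC(2,k) — across the repeat acquisitions of each subject, both groups
  pooled (scan–rescan variability is assumed group-independent).

With the customary cutoff of 0.8 on both, each feature falls into one of
four classes: 1 both reproducible and repeatable, 2 only reproducible,
3 only repeatable, 4 neither.  Scanning the confidence level th of the
CL_th masks gives per-threshold class counts, from which the optimal
threshold th_opt is the one minimizing the class-4 count (ties broken by
maximizing class 1, then by the smallest th).

Both ICC forms are computed directly from the two-way ANOVA mean squares:
``ICC(3,k) = (MS_R − MS_E) / MS_R`` and
``ICC(2,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E) / n)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteDesignError, InputError, ParameterError

__all__ = [
    "anova_mean_squares",
    "icc_consistency",
    "icc_agreement",
    "classify_stability",
    "ThresholdScan",
    "threshold_scan",
    "baseline_analysis",
    "select_thopt",
    "wilcoxon_compare",
]


def _check_design(data: np.ndarray) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise InputError("reliability design must be a 2-D table (targets × raters)")
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise InputError("need >= 3 targets and >= 2 raters")
    if np.isnan(x).any():
        raise IncompleteDesignError("design contains missing cells")
    return x


def anova_mean_squares(data: np.ndarray) -> Tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the two-way crossed layout."""
    x = _check_design(data)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_err)


def icc_consistency(data: np.ndarray) -> float:
    """Average-measure consistency ICC(3,k); NaN when between-target
    variance vanishes (undefined ICC)."""
    ms_r, _, ms_e = anova_mean_squares(data)
    if ms_r <= 0:
        return float("nan")
    return (ms_r - ms_e) / ms_r


def icc_agreement(data: np.ndarray) -> float:
    """Average-measure absolute-agreement ICC(2,k); NaN when undefined."""
    x = _check_design(np.asarray(data, dtype=float))
    n = x.shape[0]
    ms_r, ms_c, ms_e = anova_mean_squares(x)
    denom = ms_r + (ms_c - ms_e) / n
    if ms_r <= 0 or denom == 0:
        return float("nan")
    return (ms_r - ms_e) / denom


def classify_stability(icc_s: float, icc_a: float, cutoff: float = 0.8) -> int:
    """Four-class taxonomy; boundary inclusive, NaN counts below cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ParameterError("cutoff must lie in (0, 1)")
    s_ok = (not np.isnan(icc_s)) and icc_s >= cutoff
    a_ok = (not np.isnan(icc_a)) and icc_a >= cutoff
    if s_ok and a_ok:
        return 1
    if s_ok:
        return 2
    if a_ok:
        return 3
    return 4


# --------------------------------------------------------------------------
# table-level machinery

_KEYS = ["subject_id", "group", "repeat_index", "mask_source"]


def _feature_cols(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c not in _KEYS]


def _pivot(table: pd.DataFrame, source: str, feature: str) -> pd.DataFrame:
    """subjects × repeats table of one feature under one mask source."""
    sub = table[table["mask_source"] == source]
    return sub.pivot(index="subject_id", columns="repeat_index", values=feature)


def _require_complete(wide: pd.DataFrame, what: str) -> np.ndarray:
    if wide.isna().any().any():
        missing = [
            f"({wide.index[i]}, repeat {wide.columns[j]})"
            for i, j in zip(*np.where(wide.isna().values))
        ]
        raise IncompleteDesignError(f"{what}: missing cells {missing}")
    return wide.values


def icc_repeatability(table: pd.DataFrame, source: str, feature: str) -> float:
    """ICC_A of one feature across repeats, subjects pooled over groups."""
    wide = _pivot(table, source, feature)
    return icc_agreement(_require_complete(wide, f"ICC_A {feature} [{source}]"))


def icc_reproducibility(
    table: pd.DataFrame, source: str, feature: str, group: str, gt_source: str = "GT"
) -> float:
    """ICC_S of one feature between GT and a method's masks, rows = the
    individual scans (subject × repeat) of one group."""
    sub = table[table["group"] == group]
    a = sub[sub["mask_source"] == gt_source].set_index(["subject_id", "repeat_index"])[
        feature
    ]
    b = sub[sub["mask_source"] == source].set_index(["subject_id", "repeat_index"])[
        feature
    ]
    wide = pd.concat({gt_source: a, source: b}, axis=1)
    return icc_consistency(
        _require_complete(wide, f"ICC_S {feature} [{source} vs {gt_source}, {group}]")
    )


@dataclass
class ThresholdScan:
    """Per-threshold ICCs, classes and class counts, plus th_opt per group."""

    icc: pd.DataFrame  # columns: group, th, feature, icc_s, icc_a, stability_class
    class_counts: pd.DataFrame  # index (group, th), columns n1..n4
    th_opt: Dict[str, float]  # per group
    cutoff: float = 0.8

    def counts_for(self, group: str, th: float) -> Tuple[int, int, int, int]:
        row = self.class_counts.loc[(group, th)]
        return tuple(int(row[f"n{c}"]) for c in (1, 2, 3, 4))

    def features_in_classes(
        self, group: str, th: float, classes: Iterable[int]
    ) -> List[str]:
        sub = self.icc
        sel = sub[
            (sub["group"] == group)
            & (sub["th"] == th)
            & (sub["stability_class"].isin(list(classes)))
        ]
        return sorted(sel["feature"].tolist())


def _count_classes(classes: Sequence[int]) -> Dict[str, int]:
    return {f"n{c}": int(sum(cl == c for cl in classes)) for c in (1, 2, 3, 4)}


def threshold_scan(
    table: pd.DataFrame,
    thresholds: Sequence[float],
    gt_source: str = "GT",
    source_for: Optional[Mapping[float, str]] = None,
    cutoff: float = 0.8,
) -> ThresholdScan:
    """Scan confidence levels: per th and feature, ICC_S (per group, GT vs
    CL_th masks, rows = scans) and ICC_A (pooled subjects × repeats on the
    CL_th masks); classify and count per group; select th_opt per group.

    ``source_for`` maps a threshold to its mask_source label (default
    ``CL_{th:g}``).
    """
    source_for = dict(source_for or {th: f"CL_{th:g}" for th in thresholds})
    features = _feature_cols(table)
    groups = sorted(table["group"].unique())
    records = []
    for th in thresholds:
        source = source_for[th]
        icc_a = {f: icc_repeatability(table, source, f) for f in features}
        for g in groups:
            for f in features:
                icc_s = icc_reproducibility(table, source, f, g, gt_source)
                records.append(
                    {
                        "group": g,
                        "th": th,
                        "feature": f,
                        "icc_s": icc_s,
                        "icc_a": icc_a[f],
                        "stability_class": classify_stability(icc_s, icc_a[f], cutoff),
                    }
                )
    icc = pd.DataFrame(records)
    counts = (
        icc.groupby(["group", "th"])["stability_class"]
        .apply(lambda s: pd.Series(_count_classes(s.tolist())))
        .unstack()
    )
    th_opt = {
        g: select_thopt(
            {th: tuple(counts.loc[(g, th)][[f"n{c}" for c in (1, 2, 3, 4)]]) for th in thresholds}
        )
        for g in groups
    }
    return ThresholdScan(icc=icc, class_counts=counts, th_opt=th_opt, cutoff=cutoff)


def baseline_analysis(
    table: pd.DataFrame,
    auto_source: str = "MP",
    gt_source: str = "GT",
    cutoff: float = 0.8,
) -> pd.DataFrame:
    """Uncertainty-blind analysis: ICC_S between GT and the deterministic
    masks; ICC_A from either mask source separately.  Returns one row per
    (method ∈ {gt_source, auto_source}, group, feature)."""
    features = _feature_cols(table)
    groups = sorted(table["group"].unique())
    records = []
    for method in (gt_source, auto_source):
        icc_a = {f: icc_repeatability(table, method, f) for f in features}
        for g in groups:
            for f in features:
                icc_s = icc_reproducibility(table, auto_source, f, g, gt_source)
                records.append(
                    {
                        "method": method,
                        "group": g,
                        "feature": f,
                        "icc_s": icc_s,
                        "icc_a": icc_a[f],
                        "stability_class": classify_stability(icc_s, icc_a[f], cutoff),
                    }
                )
    return pd.DataFrame(records)


def select_thopt(counts: Mapping[float, Tuple[int, int, int, int]]) -> float:
    """Optimal confidence level: argmin n4, ties broken by argmax n1, then
    by the smallest threshold (deterministic)."""
    if not counts:
        raise InputError("empty threshold scan")
    return min(counts, key=lambda th: (counts[th][3], -counts[th][0], th))


def wilcoxon_compare(
    icc_values_a: Sequence[float], icc_values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-tailed paired Wilcoxon signed-rank test over features.

    Zero differences are handled with the Pratt policy; an exact null is
    used for n ≤ 25 without zeros, the normal approximation with
    continuity correction otherwise.  All-zero differences are degenerate:
    (0.0, 1.0) is returned.
    """
    a = np.asarray(icc_values_a, dtype=float)
    b = np.asarray(icc_values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    d = a - b
    if not d.size or np.all(d == 0):
        return 0.0, 1.0
    if np.any(d == 0):
        res = stats.wilcoxon(a, b, zero_method="pratt", correction=True,
                             method="approx", alternative="two-sided")
    elif d.size <= 25:
        res = stats.wilcoxon(a, b, method="exact", alternative="two-sided")
    else:
        res = stats.wilcoxon(a, b, correction=True, method="approx",
                             alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
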