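"""ICC computations, stability classes, threshold selection, Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radstab.errors import IncompleteDesignError, InputError
from radstab.stability import (
    anova_mean_squares,
    baseline_analysis,
    classify_stability,
    icc_agreement,
    icc_consistency,
    select_thopt,
    threshold_scan,
    wilcoxon_compare,
)


def pingouin_icc(x):
    """Independent oracle: pingouin's ICC(C,k) and ICC(A,k)."""
    import pingouin as pg

    n, k = x.shape
    df = pd.DataFrame(
        {
            "t": np.repeat(np.arange(n), k),
            "r": np.tile(np.arange(k), n),
            "v": x.ravel(),
        }
    )
    res = pg.intraclass_corr(df, targets="t", raters="r", ratings="v")
    res = res.set_index("Type")
    return float(res.loc["ICC(C,k)", "ICC"]), float(res.loc["ICC(A,k)", "ICC"])


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        assert icc_consistency(x) == pytest.approx(1.0)
        assert icc_agreement(x) == pytest.approx(1.0)

    def test_offsets_ignored_by_consistency_only(self):
        rows = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.stack([rows, rows + 1.0], axis=1)  # pure rater offset
        assert icc_consistency(x) == pytest.approx(1.0)
        # hand evaluation of ICC(2,k) on this 4x2 table:
        ms_r, ms_c, ms_e = anova_mean_squares(x)
        expected = (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / 4)
        agree = icc_agreement(x)
        assert agree == pytest.approx(expected)
        assert agree < 1.0
        assert agree < icc_consistency(x)

    @pytest.mark.parametrize("shape", [(10, 2), (10, 5), (6, 3)])
    def test_matches_pingouin_oracle(self, shape, rng):
        for _ in range(10):
            x = rng.normal(size=shape) + rng.normal(size=(shape[0], 1))
            c_ref, a_ref = pingouin_icc(x)
            assert abs(icc_consistency(x) - c_ref) <= 1e-10
            assert abs(icc_agreement(x) - a_ref) <= 1e-10

    def test_degenerate_rows_undefined(self):
        x = np.ones((4, 3))
        assert np.isnan(icc_consistency(x))
        assert np.isnan(icc_agreement(x))

    def test_parameter_recovery_spearman_brown(self, rng):
        # y_ij = b_i + e_ij; average-measure reliability of k repeats is
        # sigma_b^2 / (sigma_b^2 + sigma_w^2 / k)
        n, k = 200, 5
        sb, sw = 1.0, 1.2
        x = sb * rng.normal(size=(n, 1)) + sw * rng.normal(size=(n, k))
        theory = sb**2 / (sb**2 + sw**2 / k)
        assert icc_agreement(x) == pytest.approx(theory, abs=0.05)

    def test_design_validation(self):
        with pytest.raises(InputError):
            icc_consistency(np.ones((2, 2)))
        with pytest.raises(IncompleteDesignError):
            icc_agreement(np.array([[1.0, np.nan], [2, 3], [4, 5]]))


class TestClassify:
    @pytest.mark.parametrize(
        "s, a, expected",
        [
            (0.9, 0.9, 1),
            (0.9, 0.5, 2),
            (0.5, 0.9, 3),
            (0.5, 0.5, 4),
            (0.8, 0.8, 1),  # boundary inclusive
            (float("nan"), float("nan"), 4),
        ],
    )
    def test_taxonomy(self, s, a, expected):
        assert classify_stability(s, a) == expected


class TestSelectThopt:
    def test_printed_rule_with_tie(self):
        counts = {60: (5, 0, 0, 10), 80: (6, 0, 0, 8), 90: (7, 0, 0, 8)}
        assert select_thopt(counts) == 90  # min n4 tie {80,90}; max n1 -> 90

    def test_unique_minimizer(self):
        assert select_thopt({10: (0, 0, 0, 5), 50: (0, 0, 0, 2)}) == 50

    def test_full_tie_falls_to_smallest(self):
        counts = {th: (1, 1, 1, 1) for th in (30, 20, 10)}
        assert select_thopt(counts) == 10


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        stat, p = wilcoxon_compare([0.5] * 10, [0.5] * 10)
        assert (stat, p) == (0.0, 1.0)

    def test_uniform_positive_shift_significant(self, rng):
        a = rng.random(20)
        stat, p = wilcoxon_compare(a + 0.1, a)
        assert p < 0.05

    def test_pvalue_matches_exhaustive_enumeration(self, rng):
        n = 8
        d = rng.normal(size=n)
        while len(np.unique(np.abs(d))) < n:  # keep ranks tie-free
            d = rng.normal(size=n)
        a = np.zeros(n)
        stat, p = wilcoxon_compare(a + d, a)
        # enumerate all sign assignments of the ranked |d|
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w_plus = sum(r for r, s in zip(ranks, signs) if s)
            if min(w_plus, ranks.sum() - w_plus) <= w_obs:
                count += 1
        assert stat == w_obs
        assert p == pytest.approx(count / 2**n)


def make_table(rng, n_subj=4, n_rep=3, features=("f1", "f2"), noise=0.0):
    rows = []
    for g, subs in (("CKD", range(n_subj)), ("HC", range(n_subj))):
        for s in subs:
            base = {f: 10.0 * (i + 1) + s + (5 if g == "HC" else 0)
                    for i, f in enumerate(features)}
            for r in range(1, n_rep + 1):
                for src in ("GT", "MP", "CL_50", "CL_80"):
                    rows.append(
                        {
                            "subject_id": f"{g}{s}",
                            "group": g,
                            "repeat_index": r,
                            "mask_source": src,
                            **{
                                f: v + noise * rng.normal()
                                for f, v in base.items()
                            },
                        }
                    )
    return pd.DataFrame(rows)


class TestThresholdScan:
    def test_perfect_data_all_class_one(self, rng):
        table = make_table(rng, noise=0.0)
        scan = threshold_scan(table, thresholds=[50, 80])
        assert (scan.icc["stability_class"] == 1).all()
        for g in ("CKD", "HC"):
            for th in (50, 80):
                assert scan.counts_for(g, th) == (2, 0, 0, 0)

    def test_class_counts_partition_features(self, rng):
        table = make_table(rng, noise=2.0)
        scan = threshold_scan(table, thresholds=[50, 80])
        for g in ("CKD", "HC"):
            for th in (50, 80):
                assert sum(scan.counts_for(g, th)) == 2

    def test_missing_cell_named_in_error(self, rng):
        table = make_table(rng).drop(index=[6])  # (CKD0, repeat 2, CL_50)
        with pytest.raises(IncompleteDesignError, match="CKD0"):
            threshold_scan(table, thresholds=[50, 80])

    def test_baseline_analysis_shape(self, rng):
        table = make_table(rng, noise=0.5)
        base = baseline_analysis(table, auto_source="MP")
        assert set(base["method"]) == {"GT", "MP"}
        assert len(base) == 2 * 2 * 2  # methods x groups x features
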