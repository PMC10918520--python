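"""Contingency tables, accuracy metrics, ROC points and cut-offs.

The brute-force oracle here recounts raw visit rows in pure Python with
`fractions.Fraction`, independently of the pandas implementation path.
"""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from hydrascore import (
    OperatingPoint,
    Stratum,
    WUTAccuracy,
    build_contingency,
    compute_metrics,
    cutoff_value,
    evaluate_accuracy,
    roc_points,
)
from hydrascore.accuracy import ContingencyTable

from conftest import random_scored_frame


def brute_force_counts(df, marker, k, stratum=Stratum()):
    """Row-by-row recount, independent of the vectorised implementation."""
    tp = fp = fn = tn = 0
    for _, row in df.iterrows():
        if stratum.timepoint != "both" and row["timepoint"] != stratum.timepoint:
            continue
        if stratum.condition != "both" and row["condition"] != stratum.condition:
            continue
        ref = row[f"ref_{marker}"]
        if pd.isna(ref):
            continue
        test_pos = row["wut_count"] >= k
        if test_pos and ref:
            tp += 1
        elif test_pos:
            fp += 1
        elif ref:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_metrics(tp, fp, fn, tn):
    def frac(num, den):
        return Fraction(num, den) if den else None

    return (
        frac(tp, tp + fn),
        frac(tn, tn + fp),
        frac(tp, tp + fp),
        frac(tn, tn + fn),
    )


def _scored(wut_counts, refs, marker="USG"):
    n = len(wut_counts)
    df = pd.DataFrame(
        {
            "condition": ["FL"] * n,
            "timepoint": ["morning"] * n,
            "wut_count": wut_counts,
        }
    )
    df[f"ref_{marker}"] = pd.array(refs, dtype="boolean")
    return df


class TestContingency:
    def test_four_visit_example(self):
        t = build_contingency(_scored([0, 1, 2, 3], [False, False, True, True]),
                              "USG", k=2)
        assert (t.tp, t.tn, t.fp, t.fn) == (2, 2, 0, 0)

    def test_k1_with_all_counts_positive_has_no_negatives(self):
        t = build_contingency(_scored([1, 2, 3, 3], [True, False, True, False]),
                              "USG", k=1)
        assert t.fn == 0 and t.tn == 0
        assert t.tp + t.fp == 4

    def test_totals_partition_scorable_visits(self):
        refs = [True, False, None, True, None, False]
        t = build_contingency(_scored([0, 1, 2, 3, 1, 2], refs), "USG", k=2)
        assert t.total == 4  # two missing references excluded

    def test_empty_stratum_warns_and_zeroes(self):
        df = _scored([0, 1], [True, False])
        with pytest.warns(UserWarning, match="empty stratum"):
            t = build_contingency(df, "USG", 1, Stratum("afternoon", "EUH"))
        assert t.total == 0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            build_contingency(_scored([0], [True]), "USG", k=4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ContingencyTable("USG", 1, Stratum(), tp=-1, fp=0, fn=0, tn=0)


class TestMetrics:
    def test_hand_arithmetic_example(self):
        m = compute_metrics(ContingencyTable("USG", 2, Stratum(), 9, 1, 2, 8))
        assert m.sensitivity == pytest.approx(9 / 11)
        assert m.specificity == pytest.approx(8 / 9)
        assert m.ppv == pytest.approx(0.9)
        assert m.npv == pytest.approx(0.8)
        assert m.youden_j == pytest.approx(9 / 11 + 8 / 9 - 1)

    def test_no_reference_positives_is_undefined_with_reason(self):
        m = compute_metrics(ContingencyTable("USG", 1, Stratum(), 0, 3, 0, 5))
        assert m.sensitivity is None
        assert m.reasons["sensitivity"] == "no reference-positive visits"
        assert m.specificity == pytest.approx(5 / 8)
        assert m.youden_j is None

    def test_perfect_classifier(self):
        m = compute_metrics(ContingencyTable("USG", 2, Stratum(), 5, 0, 0, 7))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)
        assert "accurate at determining dehydration" in m.interpretation

    def test_oracle_equivalence_on_randomised_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            df = random_scored_frame(rng, int(rng.integers(4, 40)))
            marker = rng.choice(["USG", "UOSM", "POSM"])
            k = int(rng.integers(1, 4))
            t = build_contingency(df, marker, k)
            expected = brute_force_counts(df, marker, k)
            assert (t.tp, t.fp, t.fn, t.tn) == expected
            m = compute_metrics(t)
            for got, want in zip(
                (m.sensitivity, m.specificity, m.ppv, m.npv),
                brute_force_metrics(*expected),
            ):
                if want is None:
                    assert got is None
                else:
                    assert Fraction(got).limit_denominator(10**9) == want

    def test_metrics_match_sklearn_confusion_matrix(self, strong_cohort):
        sklearn = pytest.importorskip("sklearn.metrics")
        res = WUTAccuracy(strong_cohort).fit()
        sub = res.scored
        y_true = sub["ref_UOSM"].astype(bool).to_numpy()
        for k in (1, 2, 3):
            y_pred = (sub["wut_count"] >= k).to_numpy()
            tn, fp, fn, tp = sklearn.confusion_matrix(y_true, y_pred).ravel()
            row = res.metrics[
                (res.metrics.marker == "UOSM")
                & (res.metrics.k == k)
                & (res.metrics.timepoint == "both")
                & (res.metrics.condition == "both")
            ].iloc[0]
            assert (row.TP, row.FP, row.FN, row.TN) == (tp, fp, fn, tn)
            assert row.sensitivity == pytest.approx(tp / (tp + fn))
            assert row.specificity == pytest.approx(tn / (tn + fp))


class TestROC:
    def test_perfect_separation_puts_every_k_at_corner(self):
        df = _scored([3, 3, 0, 0], [True, True, False, False])
        pts = roc_points(df, "USG")
        for p in pts:
            if p.k is not None:
                assert (p.fpr, p.tpr) == (0.0, 1.0)

    def test_constant_wut_count_collapses_points(self):
        low = roc_points(_scored([0, 0, 0], [True, False, True]), "USG")
        high = roc_points(_scored([3, 3, 3], [True, False, True]), "USG")
        assert all((p.fpr, p.tpr) == (0.0, 0.0) for p in low if p.k is not None)
        assert all((p.fpr, p.tpr) == (1.0, 1.0) for p in high if p.k is not None)

    def test_anchors_always_present(self):
        pts = roc_points(_scored([0, 1, 2], [True, False, None]), "USG")
        assert (pts[0].fpr, pts[0].tpr) == (0.0, 0.0)
        assert (pts[-1].fpr, pts[-1].tpr) == (1.0, 1.0)
        assert len(pts) == 5

    def test_degenerate_class_yields_undefined_coordinates(self):
        pts = roc_points(_scored([0, 2, 3], [True, True, True]), "USG")
        for p in pts:
            if p.k is not None:
                assert p.fpr is None and "negative" in p.reason

    def test_points_match_brute_force_recount(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            df = random_scored_frame(rng, int(rng.integers(5, 30)))
            pts = roc_points(df, "UOSM")
            for p in pts:
                if p.k is None:
                    continue
                tp, fp, fn, tn = brute_force_counts(df, "UOSM", p.k)
                sens, spec, _, _ = brute_force_metrics(tp, fp, fn, tn)
                assert p.tpr == pytest.approx(float(sens))
                assert p.fpr == pytest.approx(1 - float(spec))

    def test_sklearn_roc_curve_cross_check(self, strong_cohort):
        sklearn = pytest.importorskip("sklearn.metrics")
        res = WUTAccuracy(strong_cohort).fit()
        sub = res.scored
        fpr, tpr, thr = sklearn.roc_curve(
            sub["ref_USG"].astype(bool), sub["wut_count"]
        )
        ours = {
            p.k: (p.fpr, p.tpr)
            for p in roc_points(sub, "USG")
            if p.k is not None
        }
        for f, t, cut in zip(fpr, tpr, thr):
            if cut in ours:
                assert ours[cut][0] == pytest.approx(f)
                assert ours[cut][1] == pytest.approx(t)


class TestCutoff:
    def _points(self, triples):
        return [
            OperatingPoint(k=k, fpr=1 - spec, tpr=sens)
            for k, sens, spec in triples
        ]

    def test_youden_enumeration_example(self):
        pts = self._points([(1, 0.9, 0.5), (2, 0.8, 0.9), (3, 0.4, 1.0)])
        cut = cutoff_value(pts, "youden")
        assert cut.value == pytest.approx(0.7)
        assert cut.k == 2

    def test_single_perfect_point(self):
        pts = [OperatingPoint(k=2, fpr=0.0, tpr=1.0)]
        assert cutoff_value(pts, "youden").value == pytest.approx(1.0)
        assert cutoff_value(pts, "closest_to_01").value == pytest.approx(0.0)

    def test_criteria_can_select_different_k(self):
        # youden: k=1 (0.45 vs 0.40); distance: k=2 (0.447 vs 0.55)
        pts = self._points([(1, 1.0, 0.45), (2, 0.6, 0.8)])
        assert cutoff_value(pts, "youden").k == 1
        cut = cutoff_value(pts, "closest_to_01")
        assert cut.k == 2
        assert cut.value == pytest.approx(np.hypot(0.2, 0.4))

    def test_ties_break_toward_larger_k(self):
        pts = self._points([(1, 0.9, 0.8), (3, 0.8, 0.9)])
        assert cutoff_value(pts, "youden").k == 3

    def test_all_undefined_yields_undefined(self):
        pts = [OperatingPoint(k=1, fpr=None, tpr=None, reason="empty")]
        cut = cutoff_value(pts, "youden")
        assert cut.value is None and cut.reason is not None

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="criterion"):
            cutoff_value([], "auc")


class TestThresholdFamily:
    def test_sensitivity_specificity_monotone_in_k(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            df = random_scored_frame(rng, int(rng.integers(10, 60)))
            for marker in ("USG", "UOSM", "POSM"):
                rows = [
                    compute_metrics(build_contingency(df, marker, k))
                    for k in (1, 2, 3)
                ]
                sens = [m.sensitivity for m in rows if m.sensitivity is not None]
                spec = [m.specificity for m in rows if m.specificity is not None]
                assert all(a >= b for a, b in zip(sens, sens[1:]))
                assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_pooled_counts_equal_sum_of_strata(self, default_cohort):
        res = WUTAccuracy(default_cohort).fit()
        m = res.metrics
        for marker in ("USG", "UOSM", "POSM"):
            for k in (1, 2, 3):
                cell = m[(m.marker == marker) & (m.k == k)].set_index(
                    ["timepoint", "condition"]
                )
                for count in ("TP", "FP", "FN", "TN"):
                    pooled = cell.loc[("both", "both"), count]
                    per_tp = (
                        cell.loc[("morning", "both"), count]
                        + cell.loc[("afternoon", "both"), count]
                    )
                    per_cond = (
                        cell.loc[("morning", "EUH"), count]
                        + cell.loc[("afternoon", "EUH"), count]
                        + cell.loc[("morning", "FL"), count]
                        + cell.loc[("afternoon", "FL"), count]
                    )
                    assert pooled == per_tp == per_cond


class TestModelObject:
    def test_fit_returns_full_grid(self, default_cohort):
        res = WUTAccuracy(default_cohort).fit()
        assert len(res.metrics) == 3 * 3 * 7  # markers x k x default strata
        assert set(res.tables) == {
            (m, k, s)
            for m in ("USG", "UOSM", "POSM")
            for k in (1, 2, 3)
            for s in res.model.strata
        }

    def test_usg_tables_keep_full_totals_posm_shrinks(self, default_cohort):
        res = WUTAccuracy(default_cohort).fit()
        m = res.metrics
        overall = m[(m.timepoint == "both") & (m.condition == "both")]
        totals = overall.groupby("marker")[["TP", "FP", "FN", "TN"]].sum().sum(axis=1)
        assert totals["USG"] == 3 * 288 and totals["UOSM"] == 3 * 288
        assert totals["POSM"] == 3 * 271

    def test_criterion_echoed_in_output(self, default_cohort):
        res = WUTAccuracy(default_cohort, criterion="closest_to_01").fit()
        assert (res.metrics["criterion"] == "closest_to_01").all()

    def test_from_csv_matches_in_memory(self, default_cohort, tmp_path):
        from hydrascore import write_visits

        path = tmp_path / "visits.csv"
        write_visits(default_cohort, path, with_truth=False)
        res_csv = WUTAccuracy.from_csv(path).fit()
        res_mem = WUTAccuracy(default_cohort).fit()
        pd.testing.assert_frame_equal(
            res_csv.metrics, res_mem.metrics, check_exact=False, atol=1e-9
        )
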