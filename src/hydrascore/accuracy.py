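"""Diagnostic accuracy of the WUT composite against reference standards.

For each reference marker, WUT threshold ``k`` (test-positive means
``wut_count >= k``) and stratum, a 2×2 contingency table is built with
reference-dehydrated as the positive class.  From each table come
sensitivity, specificity, PPV and NPV with explicit handling of empty
denominators; the three thresholds form an ROC with anchors (0,0) and
(1,1), and a cut-off determination value summarises the curve either by
the Youden index (sensitivity + specificity − 1, maximised) or by the
distance to the ideal corner (0,1) (minimised).

High sensitivity means the composite is accurate at establishing
euhydration (a negative rules dehydration out); high specificity means it
is accurate at establishing dehydration (a positive rules it in).

The statsmodels-style entry point is :class:`WUTAccuracy` — built from a
visits frame, its :meth:`WUTAccuracy.fit` returns a
:class:`WUTAccuracyResults` carrying the tables, metrics, ROC points and a
``summary()`` report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import hypot
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .config import (
    REFERENCE_MARKERS,
    ReferenceThresholds,
    WUTThresholds,
)
from .reference import classify_visits
from .scoring import compute_baselines, score_visits


@dataclass(frozen=True)
class Stratum:
    """A (timepoint, condition) analysis cell; ``"both"`` pools levels."""

    timepoint: str = "both"
    condition: str = "both"

    def mask(self, df: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=df.index)
        if self.timepoint != "both":
            m &= df["timepoint"] == self.timepoint
        if self.condition != "both":
            m &= df["condition"] == self.condition
        return m

    @property
    def label(self) -> str:
        return f"{self.timepoint}/{self.condition}"


#: Default strata: per-timepoint pooled, per timepoint x condition, overall.
DEFAULT_STRATA: Tuple[Stratum, ...] = (
    Stratum("morning", "both"),
    Stratum("afternoon", "both"),
    Stratum("morning", "EUH"),
    Stratum("afternoon", "EUH"),
    Stratum("morning", "FL"),
    Stratum("afternoon", "FL"),
    Stratum("both", "both"),
)


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: positive = reference-dehydrated, test = wut_count >= k."""

    marker: str
    k: int
    stratum: Stratum
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyMetrics:
    """Proportions from one table; undefined metrics carry a reason."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    reasons: Dict[str, str] = field(default_factory=dict)

    @property
    def youden_j(self) -> Optional[float]:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1.0

    @property
    def interpretation(self) -> str:
        parts = []
        if self.sensitivity is not None and self.sensitivity >= 0.8:
            parts.append("high sensitivity: accurate at determining euhydration")
        if self.specificity is not None and self.specificity >= 0.8:
            parts.append("high specificity: accurate at determining dehydration")
        return "; ".join(parts) if parts else "no high-accuracy interpretation"


def build_contingency(
    scored: pd.DataFrame,
    marker: str,
    k: int,
    stratum: Stratum = Stratum(),
) -> ContingencyTable:
    """Count TP/FP/FN/TN for one (marker, k, stratum) cell.

    ``scored`` must carry ``wut_count`` and the nullable-boolean
    ``ref_<marker>`` column.  Visits with a missing reference call are
    excluded listwise for that marker only, so urinary tables keep their
    full totals while plasma tables shrink by the missing count.
    """
    if marker not in REFERENCE_MARKERS:
        raise KeyError(f"unknown reference marker {marker!r}")
    if k not in (1, 2, 3):
        raise ValueError(f"wut threshold k must be 1, 2 or 3, got {k}")
    sub = scored[stratum.mask(scored)]
    ref = sub[f"ref_{marker}"]
    sub = sub[ref.notna()]
    if sub.empty:
        warnings.warn(
            f"empty stratum {stratum.label} for marker {marker}; table of zeros",
            stacklevel=2,
        )
        return ContingencyTable(marker, k, stratum, 0, 0, 0, 0)
    ref_pos = sub[f"ref_{marker}"].astype(bool)
    test_pos = sub["wut_count"] >= k
    return ContingencyTable(
        marker=marker,
        k=k,
        stratum=stratum,
        tp=int((test_pos & ref_pos).sum()),
        fp=int((test_pos & ~ref_pos).sum()),
        fn=int((~test_pos & ref_pos).sum()),
        tn=int((~test_pos & ~ref_pos).sum()),
    )


def _ratio(num: int, den: int, name: str, reason: str, reasons: Dict[str, str]):
    if den == 0:
        reasons[name] = reason
        return None
    return num / den


def compute_metrics(table: ContingencyTable) -> AccuracyMetrics:
    """Sensitivity, specificity, PPV and NPV from a 2×2 table.

    A zero denominator yields ``None`` with a reason (for instance a
    stratum with no reference-positive visit has undefined sensitivity) —
    never a silent zero or NaN.
    """
    reasons: Dict[str, str] = {}
    return AccuracyMetrics(
        sensitivity=_ratio(
            table.tp, table.tp + table.fn, "sensitivity",
            "no reference-positive visits", reasons,
        ),
        specificity=_ratio(
            table.tn, table.tn + table.fp, "specificity",
            "no reference-negative visits", reasons,
        ),
        ppv=_ratio(
            table.tp, table.tp + table.fp, "ppv",
            "no test-positive visits", reasons,
        ),
        npv=_ratio(
            table.tn, table.tn + table.fn, "npv",
            "no test-negative visits", reasons,
        ),
        reasons=reasons,
    )


@dataclass(frozen=True)
class OperatingPoint:
    """One ROC point: (1 − specificity, sensitivity) at threshold k.

    Anchors carry ``k=None``.  Degenerate strata (a reference class with
    no member) leave the affected coordinate ``None`` with a reason.
    """

    k: Optional[int]
    fpr: Optional[float]
    tpr: Optional[float]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.fpr is not None and self.tpr is not None


def roc_points(
    scored: pd.DataFrame,
    marker: str,
    stratum: Stratum = Stratum(),
    ks: Sequence[int] = (1, 2, 3),
) -> List[OperatingPoint]:
    """Ordered ROC operating points for the WUT thresholds.

    Returns the (0,0) anchor, one point per k from most to least specific
    (so false-positive rate is non-decreasing along the list), and the
    (1,1) anchor.
    """
    points = [OperatingPoint(k=None, fpr=0.0, tpr=0.0)]
    for k in sorted(ks, reverse=True):
        table = build_contingency(scored, marker, k, stratum)
        m = compute_metrics(table)
        reason = "; ".join(
            m.reasons[key] for key in ("sensitivity", "specificity") if key in m.reasons
        ) or None
        points.append(
            OperatingPoint(
                k=k,
                fpr=None if m.specificity is None else 1.0 - m.specificity,
                tpr=m.sensitivity,
                reason=reason,
            )
        )
    points.append(OperatingPoint(k=None, fpr=1.0, tpr=1.0))
    return points


@dataclass(frozen=True)
class CutoffResult:
    """Cut-off determination value and the WUT threshold achieving it."""

    value: Optional[float]
    k: Optional[int]
    criterion: str
    reason: Optional[str] = None


def cutoff_value(
    points: Sequence[OperatingPoint],
    criterion: str = "youden",
) -> CutoffResult:
    """Summarise an ROC into a single cut-off determination value.

    ``youden`` maximises sensitivity + specificity − 1 over the WUT
    thresholds; ``closest_to_01`` minimises the Euclidean distance to the
    ideal corner (0,1).  Ties break toward the larger k (the more specific
    call).  Anchors and undefined points are ignored; all points undefined
    yields an undefined result with a reason.
    """
    if criterion not in ("youden", "closest_to_01"):
        raise ValueError(f"unknown cut-off criterion {criterion!r}")
    best: Optional[Tuple[float, int]] = None
    for p in points:
        if p.k is None or not p.defined:
            continue
        score = (
            p.tpr - p.fpr
            if criterion == "youden"
            else hypot(p.fpr, 1.0 - p.tpr)
        )
        if best is None:
            best = (score, p.k)
            continue
        better = score > best[0] if criterion == "youden" else score < best[0]
        tie = score == best[0]
        if better or (tie and p.k > best[1]):
            best = (score, p.k)
    if best is None:
        return CutoffResult(
            value=None, k=None, criterion=criterion,
            reason="no defined operating point",
        )
    return CutoffResult(value=best[0], k=best[1], criterion=criterion)


def evaluate_accuracy(
    scored: pd.DataFrame,
    strata: Sequence[Stratum] = DEFAULT_STRATA,
    ks: Sequence[int] = (1, 2, 3),
    criterion: str = "youden",
    flag_threshold: float = 0.8,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[Tuple[str, int, Stratum], ContingencyTable]]:
    """Full metric grid over markers × k × strata.

    Returns ``(metrics, roc, tables)``: a long metrics frame (one row per
    marker/k/stratum with counts, the four proportions, Youden J, the
    stratum's cut-off value and the practical-significance flags), a long
    ROC-point frame, and the raw contingency tables.  The flags mark
    sensitivity (resp. specificity) exceeding both the cut-off
    determination value and the ``flag_threshold`` (0.800 by default).
    """
    metric_rows = []
    roc_rows = []
    tables: Dict[Tuple[str, int, Stratum], ContingencyTable] = {}
    for marker in REFERENCE_MARKERS:
        for stratum in strata:
            pts = roc_points(scored, marker, stratum, ks)
            cut = cutoff_value(pts, criterion)
            for p in pts:
                roc_rows.append(
                    {
                        "marker": marker,
                        "timepoint": stratum.timepoint,
                        "condition": stratum.condition,
                        "k": p.k,
                        "fpr": p.fpr,
                        "tpr": p.tpr,
                        "reason": p.reason,
                    }
                )
            for k in ks:
                table = build_contingency(scored, marker, k, stratum)
                tables[(marker, k, stratum)] = table
                m = compute_metrics(table)

                def _flag(value: Optional[float]) -> bool:
                    return (
                        value is not None
                        and cut.value is not None
                        and value > cut.value
                        and value > flag_threshold
                    )

                metric_rows.append(
                    {
                        "marker": marker,
                        "k": k,
                        "timepoint": stratum.timepoint,
                        "condition": stratum.condition,
                        "TP": table.tp,
                        "FP": table.fp,
                        "FN": table.fn,
                        "TN": table.tn,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "ppv": m.ppv,
                        "npv": m.npv,
                        "youden_j": m.youden_j,
                        "cutoff_value": cut.value,
                        "cutoff_k": cut.k,
                        "criterion": criterion,
                        "sens_flag": _flag(m.sensitivity),
                        "spec_flag": _flag(m.specificity),
                        "sens_reason": m.reasons.get("sensitivity"),
                        "spec_reason": m.reasons.get("specificity"),
                        "ppv_reason": m.reasons.get("ppv"),
                        "npv_reason": m.reasons.get("npv"),
                    }
                )
    return pd.DataFrame(metric_rows), pd.DataFrame(roc_rows), tables


class WUTAccuracy:
    """Diagnostic-accuracy model of the WUT composite for a visits frame.

    Parameters
    ----------
    visits : DataFrame
        Long-format visit records (one row per subject/condition/day/
        timepoint with the six-marker panel).
    wut_thresholds, ref_thresholds : optional
        Override the composite or reference-standard thresholds.
    baselines : DataFrame, optional
        External per-subject baselines (columns ``subject_id``,
        ``baseline_bm_kg``); computed from the euhydrated-morning visits
        when omitted.
    strata : sequence of Stratum
        Analysis cells; defaults to per-timepoint (pooled and per
        condition) plus the overall pool.
    criterion : {"youden", "closest_to_01"}
        Cut-off determination rule.
    flag_threshold : float
        Practical-significance bound for the sensitivity/specificity flags.

    Examples
    --------
    >>> from hydrascore import SimConfig, simulate, WUTAccuracy
    >>> results = WUTAccuracy(simulate(SimConfig(rng_seed=7))).fit()
    >>> print(results.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        visits: pd.DataFrame,
        wut_thresholds: WUTThresholds | None = None,
        ref_thresholds: ReferenceThresholds | None = None,
        baselines: pd.DataFrame | None = None,
        strata: Sequence[Stratum] = DEFAULT_STRATA,
        ks: Sequence[int] = (1, 2, 3),
        criterion: str = "youden",
        flag_threshold: float = 0.8,
    ) -> None:
        self.visits = visits
        self.wut_thresholds = wut_thresholds or WUTThresholds()
        self.ref_thresholds = ref_thresholds or ReferenceThresholds()
        self.baselines = (
            baselines if baselines is not None else compute_baselines(visits)
        )
        self.strata = tuple(strata)
        self.ks = tuple(ks)
        self.criterion = criterion
        self.flag_threshold = flag_threshold

    @classmethod
    def from_csv(cls, path, **kwargs) -> "WUTAccuracy":
        """Build the model from a visits CSV (validated on read)."""
        from .report import read_visits

        return cls(read_visits(path), **kwargs)

    def fit(self) -> "WUTAccuracyResults":
        """Score, classify and evaluate; returns the results object."""
        scored = score_visits(self.visits, self.wut_thresholds, self.baselines)
        scored = classify_visits(scored, self.ref_thresholds)
        metrics, roc, tables = evaluate_accuracy(
            scored, self.strata, self.ks, self.criterion, self.flag_threshold
        )
        return WUTAccuracyResults(self, scored, metrics, roc, tables)


class WUTAccuracyResults:
    """Fitted accuracy estimates: tables, metrics, ROC points, report.

    Attributes
    ----------
    scored : DataFrame
        Per-visit WUT scores joined with the three reference calls.
    metrics : DataFrame
        One row per marker × k × stratum with counts, sensitivity,
        specificity, PPV, NPV, Youden J, cut-off value and flags.
    roc : DataFrame
        Operating points (anchors included) per marker × stratum.
    tables : dict
        Raw :class:`ContingencyTable` objects keyed by (marker, k, stratum).
    """

    def __init__(self, model, scored, metrics, roc, tables) -> None:
        self.model = model
        self.scored = scored
        self.metrics = metrics
        self.roc = roc
        self.tables = tables

    @property
    def category_table(self) -> pd.DataFrame:
        """Visit counts per WUT category per stratum."""
        from .report import wut_category_table

        return wut_category_table(self.scored, self.model.strata)

    def summary(self) -> str:
        """Deterministic plain-text report (3-decimal display rounding)."""
        from .report import render_report

        return render_report(self)

    def save(self, metrics_path, roc_path=None) -> None:
        """Write the metrics (and optionally ROC points) to CSV."""
        self.metrics.to_csv(metrics_path, index=False)
        if roc_path is not None:
            self.roc.to_csv(roc_path, index=False)
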