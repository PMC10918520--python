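"""WUT composite scoring: baselines, body-mass loss and the 0–3 count.

The composite counts how many of three field markers cross their
dehydration threshold at a visit: body-mass loss relative to the subject's
euhydrated baseline (strictly more than 1 %), urine colour of 5 or darker
on the eight-point chart, and thirst of 5 or more on the nine-point scale.
Two markers met reads as "likely dehydrated", all three as "very likely
dehydrated".

Baseline body mass is the mean of a subject's euhydrated first-morning
measurements (three in the reference design).  Body-mass loss is reported
loss-positive — ``(baseline − mass) / baseline × 100`` — so that a loss is
directly comparable to the "> 1 %" criterion; a negative value means mass
was gained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import WUTThresholds

#: Category label per WUT count.
WUT_LABELS = {0: "WUT0", 1: "WUT1", 2: "WUT2", 3: "WUT3"}

#: Field interpretation of each category.
WUT_INTERPRETATION = {
    0: "dehydration unlikely",
    1: "insufficient markers",
    2: "likely dehydrated",
    3: "very likely dehydrated",
}


class MissingInputError(ValueError):
    """A WUT input (body mass, urine colour or thirst) is absent.

    WUT inputs are never imputed; callers must supply complete visits.
    """


@dataclass(frozen=True)
class SubjectBaseline:
    """Per-subject reference body mass.

    ``n_baseline_visits`` records how many euhydrated-morning measurements
    the mean is based on; fewer than three is flagged, not fatal, so that
    datasets without a full euhydrated arm stay scorable.
    """

    subject_id: str
    baseline_bm_kg: float
    n_baseline_visits: int

    def __post_init__(self) -> None:
        if self.baseline_bm_kg <= 0:
            raise ValueError(
                f"baseline body mass must be > 0 for {self.subject_id}"
            )
        if self.n_baseline_visits < 1:
            raise ValueError(
                f"baseline needs >= 1 visit for {self.subject_id}"
            )

    @property
    def low_n(self) -> bool:
        """True when fewer than the three reference-design visits back the mean."""
        return self.n_baseline_visits < 3


@dataclass(frozen=True)
class WUTResult:
    """Per-visit marker flags, count and category label."""

    bml_loss_pct: float
    w_met: bool
    u_met: bool
    t_met: bool

    @property
    def wut_count(self) -> int:
        return int(self.w_met) + int(self.u_met) + int(self.t_met)

    @property
    def label(self) -> str:
        return WUT_LABELS[self.wut_count]

    @property
    def interpretation(self) -> str:
        return WUT_INTERPRETATION[self.wut_count]


def compute_baseline_bm(records: pd.DataFrame, subject_id: str) -> SubjectBaseline:
    """Mean euhydrated-morning body mass for one subject.

    Raises :class:`MissingInputError` naming the subject when no
    EUH-morning visit exists.
    """
    sel = records[
        (records["subject_id"] == subject_id)
        & (records["condition"] == "EUH")
        & (records["timepoint"] == "morning")
    ]
    masses = sel["body_mass_kg"].dropna()
    if masses.empty:
        raise MissingInputError(
            f"subject {subject_id!r} has no EUH-morning body-mass record "
            "to form a baseline"
        )
    return SubjectBaseline(
        subject_id=subject_id,
        baseline_bm_kg=float(masses.mean()),
        n_baseline_visits=int(masses.size),
    )


def compute_baselines(records: pd.DataFrame) -> pd.DataFrame:
    """Baselines for every subject with at least one EUH-morning visit.

    Returns a frame with columns ``subject_id``, ``baseline_bm_kg``,
    ``n_baseline_visits`` and ``low_n``.
    """
    rows = []
    for sid in records["subject_id"].unique():
        b = compute_baseline_bm(records, sid)
        rows.append(
            {
                "subject_id": b.subject_id,
                "baseline_bm_kg": b.baseline_bm_kg,
                "n_baseline_visits": b.n_baseline_visits,
                "low_n": b.low_n,
            }
        )
    return pd.DataFrame(rows)


def compute_bml(body_mass_kg: float, baseline: SubjectBaseline | float) -> float:
    """Loss-positive body-mass change in percent of baseline.

    ``(baseline − mass) / baseline × 100``: a 0.8 kg loss from an
    80 kg baseline is +1.0 %, a gain comes out negative.
    """
    base = baseline.baseline_bm_kg if isinstance(baseline, SubjectBaseline) else float(baseline)
    if base <= 0 or body_mass_kg <= 0:
        raise ValueError("body masses must be > 0")
    return (base - body_mass_kg) / base * 100.0


def score_wut(
    record: Mapping,
    baseline: SubjectBaseline | float,
    thresholds: WUTThresholds | None = None,
) -> WUTResult:
    """Score a single visit.

    ``record`` must provide ``body_mass_kg``, ``u_col`` and ``thirst``;
    a missing value raises :class:`MissingInputError` (never imputed).
    Weight is met strictly above the loss threshold; urine colour and
    thirst are met at or above theirs.
    """
    thresholds = thresholds or WUTThresholds()
    for field in ("body_mass_kg", "u_col", "thirst"):
        value = record.get(field) if hasattr(record, "get") else record[field]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise MissingInputError(f"visit is missing WUT input {field!r}")
    bml = compute_bml(float(record["body_mass_kg"]), baseline)
    return WUTResult(
        bml_loss_pct=bml,
        w_met=bml > thresholds.bml_loss_pct_threshold,
        u_met=int(record["u_col"]) >= thresholds.u_col_threshold,
        t_met=int(record["thirst"]) >= thresholds.thirst_threshold,
    )


def score_visits(
    records: pd.DataFrame,
    thresholds: WUTThresholds | None = None,
    baselines: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorised scoring of a visits frame.

    ``baselines`` defaults to :func:`compute_baselines` of ``records``
    (requires the euhydrated arm); pass an external frame to score
    free-living-only data.  Returns a copy with ``bml_loss_pct``,
    ``w_met``, ``u_met``, ``t_met``, ``wut_count``, ``label`` and
    ``interpretation`` appended.
    """
    thresholds = thresholds or WUTThresholds()
    if baselines is None:
        baselines = compute_baselines(records)
    for field in ("body_mass_kg", "u_col", "thirst"):
        if records[field].isna().any():
            bad = records.index[records[field].isna()].tolist()
            raise MissingInputError(
                f"WUT input {field!r} missing at rows {bad[:5]}"
            )

    base_map = baselines.set_index("subject_id")["baseline_bm_kg"]
    unknown = set(records["subject_id"]) - set(base_map.index)
    if unknown:
        raise MissingInputError(
            f"no baseline available for subjects {sorted(unknown)[:5]}"
        )
    base = records["subject_id"].map(base_map)

    out = records.copy()
    out["bml_loss_pct"] = (base - out["body_mass_kg"]) / base * 100.0
    out["w_met"] = out["bml_loss_pct"] > thresholds.bml_loss_pct_threshold
    out["u_met"] = out["u_col"] >= thresholds.u_col_threshold
    out["t_met"] = out["thirst"] >= thresholds.thirst_threshold
    out["wut_count"] = (
        out["w_met"].astype(int) + out["u_met"].astype(int) + out["t_met"].astype(int)
    )
    out["label"] = out["wut_count"].map(WUT_LABELS)
    out["interpretation"] = out["wut_count"].map(WUT_INTERPRETATION)
    return out
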