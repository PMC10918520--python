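"""CSV schemas, input validation and paper-shaped summary tables.

The single interchange format is long-format CSV (UTF-8, '.' decimal),
one row per visit; a missing plasma osmolality is an empty field.  Reads
are validated row by row and schema violations are reported with their
row numbers.  Display tables round to 3 decimals; CSV output keeps full
precision.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .cohort import TRUTH_COLUMNS, VISIT_COLUMNS
from .config import Condition, Sex, Timepoint

logger = logging.getLogger("hydrascore")


class VisitRecord(BaseModel):
    """One spot-sample observation: design coordinates plus the marker panel."""

    subject_id: str
    sex: Sex
    condition: Condition
    day: int = Field(ge=1)
    timepoint: Timepoint
    body_mass_kg: float = Field(gt=0)
    u_col: int = Field(ge=1, le=8)
    thirst: int = Field(ge=1, le=9)
    usg: float = Field(ge=1.000, le=1.100)
    u_osm: float = Field(gt=0)
    p_osm: Optional[float] = Field(default=None, gt=0)


class SchemaError(ValueError):
    """Input CSV violates the visits schema; message lists rows and fields."""


def read_visits(path) -> pd.DataFrame:
    """Read and validate a visits CSV.

    Every row is checked against :class:`VisitRecord`; violations are
    collected and raised together as :class:`SchemaError` naming the
    1-based data row and the offending field.  An empty ``p_osm`` cell
    becomes missing (NaN).  Latent truth columns, when present, are
    passed through untouched.
    """
    df = pd.read_csv(path)
    required = [c for c in VISIT_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    problems = []
    for i, row in enumerate(df[required].to_dict("records"), start=1):
        if row.get("p_osm") is not None and pd.isna(row["p_osm"]):
            row["p_osm"] = None
        try:
            VisitRecord(**row)
        except ValidationError as exc:
            for err in exc.errors():
                field = ".".join(str(loc) for loc in err["loc"])
                problems.append(f"row {i}: {field}: {err['msg']}")
    if problems:
        raise SchemaError(
            f"{len(problems)} schema violation(s):\n" + "\n".join(problems[:20])
        )

    dupes = df.duplicated(subset=["subject_id", "condition", "day", "timepoint"])
    if dupes.any():
        raise SchemaError(
            f"duplicate visit keys at rows {list(df.index[dupes] + 1)[:10]}"
        )
    for col in ("day", "u_col", "thirst"):
        df[col] = df[col].astype(int)
    if "latent_dehydrated" in df.columns:
        df["latent_dehydrated"] = df["latent_dehydrated"].astype(bool)
    return df


def write_visits(df: pd.DataFrame, path, with_truth: bool = True) -> None:
    """Write a visits frame as CSV; missing ``p_osm`` becomes an empty field.

    ``with_truth=False`` drops the latent truth columns for blinded use.
    ``usg`` is written with 3 decimals and the osmolalities as integers to
    keep round-trips byte-stable.
    """
    cols = list(VISIT_COLUMNS)
    if with_truth:
        cols += [c for c in TRUTH_COLUMNS if c in df.columns]
    out = df[cols].copy()
    out["usg"] = out["usg"].map(lambda v: f"{v:.3f}")
    out["u_osm"] = out["u_osm"].map(lambda v: f"{v:.0f}")
    out["p_osm"] = out["p_osm"].map(
        lambda v: "" if pd.isna(v) else f"{v:.0f}"
    )
    out.to_csv(path, index=False)


def wut_category_table(
    scored: pd.DataFrame, strata: Sequence = None
) -> pd.DataFrame:
    """Visit counts per WUT category (WUT0–WUT3) per stratum.

    Row sums equal the number of scored visits in each stratum.
    """
    from .accuracy import DEFAULT_STRATA, Stratum  # local: avoid cycle

    strata = list(strata) if strata is not None else list(DEFAULT_STRATA)
    rows = []
    for stratum in strata:
        sub = scored[stratum.mask(scored)]
        counts = sub["wut_count"].value_counts()
        row = {
            "timepoint": stratum.timepoint,
            "condition": stratum.condition,
        }
        for c in range(4):
            row[f"WUT{c}"] = int(counts.get(c, 0))
        row["total"] = int(len(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt(value, reason=None) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return f"NA ({reason})" if reason else "NA"
    return f"{value:.3f}"


def render_report(results) -> str:
    """Deterministic plain-text accuracy report.

    One block per stratum: the WUT category counts, then per reference
    marker and threshold the sensitivity, specificity, cut-off
    determination value, PPV and NPV.  Metrics flagged ``*`` exceed both
    the cut-off value and the practical-significance bound; undefined
    metrics render as ``NA (reason)``.  Display rounding is 3 decimals.
    """
    model = results.model
    lines = [
        "WUT diagnostic accuracy report",
        "==============================",
        f"visits: {len(model.visits)}   cut-off criterion: {model.criterion}   "
        f"flag threshold: {model.flag_threshold:.3f}",
        f"WUT thresholds: BML > {model.wut_thresholds.bml_loss_pct_threshold:g} %, "
        f"u_col >= {model.wut_thresholds.u_col_threshold}, "
        f"thirst >= {model.wut_thresholds.thirst_threshold}",
        f"reference thresholds: USG {'>=' if model.ref_thresholds.usg_comparator == 'ge' else '>'} "
        f"{model.ref_thresholds.usg_threshold:.3f}, "
        f"U_OSM > {model.ref_thresholds.u_osm_threshold:g} mOsm/kg, "
        f"P_OSM > {model.ref_thresholds.p_osm_threshold:g} mOsm/kg",
        "",
        "WUT category counts",
        "-------------------",
        results.category_table.to_string(index=False),
        "",
    ]
    metrics = results.metrics
    for (tp, cond), block in metrics.groupby(
        ["timepoint", "condition"], sort=False
    ):
        lines.append(f"stratum: timepoint={tp}, condition={cond}")
        lines.append(
            f"{'marker':<6} {'k':>2} {'sens':>12} {'spec':>12} "
            f"{'cutoff':>8} {'ppv':>12} {'npv':>12}"
        )
        for _, r in block.iterrows():
            sens = _fmt(r["sensitivity"], r["sens_reason"]) + (
                "*" if r["sens_flag"] else ""
            )
            spec = _fmt(r["specificity"], r["spec_reason"]) + (
                "*" if r["spec_flag"] else ""
            )
            lines.append(
                f"{r['marker']:<6} {r['k']:>2} {sens:>12} {spec:>12} "
                f"{_fmt(r['cutoff_value']):>8} "
                f"{_fmt(r['ppv'], r['ppv_reason']):>12} "
                f"{_fmt(r['npv'], r['npv_reason']):>12}"
            )
        lines.append("")
    lines.append(
        "* sensitivity/specificity above the cut-off determination value "
        f"and above {model.flag_threshold:.3f}"
    )
    return "\n".join(lines) + "\n"
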