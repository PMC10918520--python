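"""Binary dehydrated/euhydrated reference calls per visit.

Three laboratory standards define the reference state: urine specific
gravity at or above 1.020, urine osmolality strictly above 700 mOsm/kg,
and plasma osmolality strictly above 290 mOsm/kg.  A missing plasma
measurement propagates to a missing call — never a guess.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import REFERENCE_MARKERS, ReferenceThresholds


@dataclass(frozen=True)
class ReferenceCall:
    """One marker's dehydration call for one visit (None when unmeasured)."""

    marker: str
    dehydrated: Optional[bool]

    @property
    def missing(self) -> bool:
        return self.dehydrated is None


def _call(value: float, marker: str, thresholds: ReferenceThresholds) -> bool:
    if marker == "USG":
        if thresholds.usg_comparator == "ge":
            return value >= thresholds.usg_threshold
        return value > thresholds.usg_threshold
    if marker == "UOSM":
        return value > thresholds.u_osm_threshold
    if marker == "POSM":
        return value > thresholds.p_osm_threshold
    raise KeyError(f"unknown reference marker {marker!r}")


def classify_reference(
    record: Mapping,
    marker: str,
    thresholds: ReferenceThresholds | None = None,
) -> ReferenceCall:
    """Classify one visit against one reference marker.

    ``marker`` is one of ``USG``, ``UOSM``, ``POSM``.  A missing
    measurement yields a call with ``dehydrated=None``.
    """
    thresholds = thresholds or ReferenceThresholds()
    if marker not in REFERENCE_MARKERS:
        raise KeyError(
            f"unknown reference marker {marker!r}; expected one of "
            f"{sorted(REFERENCE_MARKERS)}"
        )
    value = record[REFERENCE_MARKERS[marker]]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ReferenceCall(marker=marker, dehydrated=None)
    return ReferenceCall(marker=marker, dehydrated=_call(float(value), marker, thresholds))


def classify_visits(
    records: pd.DataFrame,
    thresholds: ReferenceThresholds | None = None,
    format: str = "wide",
) -> pd.DataFrame:
    """Classify every visit against all three reference markers.

    ``format="wide"`` appends nullable-boolean columns ``ref_USG``,
    ``ref_UOSM`` and ``ref_POSM`` to a copy of ``records``;
    ``format="long"`` returns one row per visit × marker with columns
    ``marker`` and ``dehydrated`` (missing where unmeasured).
    """
    thresholds = thresholds or ReferenceThresholds()
    wide = records.copy()
    for marker, column in REFERENCE_MARKERS.items():
        values = records[column]
        if marker == "USG" and thresholds.usg_comparator == "ge":
            call = values >= thresholds.usg_threshold
        elif marker == "USG":
            call = values > thresholds.usg_threshold
        elif marker == "UOSM":
            call = values > thresholds.u_osm_threshold
        else:
            call = values > thresholds.p_osm_threshold
        wide[f"ref_{marker}"] = call.astype("boolean").mask(values.isna())
    if format == "wide":
        return wide
    if format != "long":
        raise ValueError(f"format must be 'wide' or 'long', got {format!r}")
    key_cols = [c for c in ("subject_id", "condition", "day", "timepoint") if c in records.columns]
    long = wide.melt(
        id_vars=key_cols,
        value_vars=[f"ref_{m}" for m in REFERENCE_MARKERS],
        var_name="marker",
        value_name="dehydrated",
    )
    long["marker"] = long["marker"].str.removeprefix("ref_")
    return long
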