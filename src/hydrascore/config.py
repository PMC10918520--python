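"""Configuration types for simulation, scoring and reference classification.

All tunable quantities of the pipeline live here as validated pydantic
models: the synthetic-cohort design and its latent-state parameters
(:class:`SimConfig`), the WUT composite thresholds (:class:`WUTThresholds`)
and the urinary/blood reference-standard thresholds
(:class:`ReferenceThresholds`).
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, Literal, Tuple

from pydantic import BaseModel, Field, model_validator

Condition = Literal["FL", "EUH"]
Timepoint = Literal["morning", "afternoon"]
Sex = Literal["M", "F"]

#: Marker keys used throughout the generator, in canonical order.
MARKERS: Tuple[str, ...] = ("bml_pct", "usg", "u_osm", "p_osm", "u_col", "thirst")

#: Reference-standard marker names and the visit columns they read.
REFERENCE_MARKERS: Dict[str, str] = {"USG": "usg", "UOSM": "u_osm", "POSM": "p_osm"}


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


class WUTThresholds(BaseModel):
    """Dehydration thresholds for the three WUT markers.

    The body-mass-loss criterion is strict (``> 1 %``) while urine colour
    and thirst are met at their boundary (``>= 5``), matching the mixed
    comparators of the composite's definition.
    """

    bml_loss_pct_threshold: float = Field(default=1.0, gt=0.0)
    u_col_threshold: int = Field(default=5, ge=1, le=8)
    thirst_threshold: int = Field(default=5, ge=1, le=9)

    model_config = {"frozen": True}


class ReferenceThresholds(BaseModel):
    """Dehydration thresholds for the reference standards.

    USG is met at the boundary (``>= 1.020`` by default; the comparator is
    exposed because the strict convention also circulates), urine and plasma
    osmolality are strict (``> 700`` / ``> 290`` mOsm/kg).
    """

    usg_threshold: float = Field(default=1.020, gt=1.000)
    usg_comparator: Literal["ge", "gt"] = "ge"
    u_osm_threshold: float = Field(default=700.0, gt=0.0)
    p_osm_threshold: float = Field(default=290.0, gt=0.0)

    model_config = {"frozen": True}


def _default_p_dehydrated() -> Dict[str, Dict[str, float]]:
    # Dehydration rarer under enforced euhydration than free living, and
    # rarer in the morning EUH visits than afternoon FL visits.
    return {
        "FL": {"morning": 0.45, "afternoon": 0.55},
        "EUH": {"morning": 0.10, "afternoon": 0.15},
    }


def _default_marker_anchor() -> Dict[str, float]:
    # Euhydrated (latent deficit z = 0) marker means.
    return {
        "bml_pct": 0.0,
        "usg": 1.010,
        "u_osm": 400.0,
        "p_osm": 285.0,
        "u_col": 3.0,
        "thirst": 3.0,
    }


def _default_marker_slope() -> Dict[str, float]:
    # Marker shift per unit latent deficit z; chosen so that z = 1 crosses
    # every dehydration threshold from the euhydrated anchor.
    return {
        "bml_pct": 1.8,
        "usg": 0.012,
        "u_osm": 450.0,
        "p_osm": 8.0,
        "u_col": 3.0,
        "thirst": 3.0,
    }


def _default_marker_noise_sd() -> Dict[str, float]:
    return {
        "bml_pct": 0.35,
        "usg": 0.004,
        "u_osm": 120.0,
        "p_osm": 3.0,
        "u_col": 1.0,
        "thirst": 1.2,
    }


def _default_missing_plasma() -> Dict[str, Dict[str, int]]:
    # Stratified counts of plasma samples lost to technical issues.
    return {
        "EUH": {"morning": 6, "afternoon": 4},
        "FL": {"morning": 4, "afternoon": 3},
    }


class SimConfig(BaseModel):
    """Synthetic-cohort design and latent-dehydration generator parameters.

    The design geometry defaults to 24 subjects (half men, half women)
    observed under two conditions (free living then enforced euhydration),
    three consecutive days per condition, morning and afternoon — 288
    visits.  A latent binary dehydration state ``D`` is drawn per visit
    from ``p_dehydrated[condition][timepoint]``; the latent deficit
    ``z = latent_deficit_scale * D + N(0, latent_noise_sd)`` then drives
    each marker linearly (``anchor + slope * z`` plus marker noise), so
    every marker deteriorates monotonically with the deficit and body mass
    falls relative to the subject's baseline.
    """

    n_subjects: int = Field(default=24, gt=0)
    n_days_per_condition: int = Field(default=3, gt=0)
    conditions: Tuple[Condition, ...] = ("FL", "EUH")
    timepoints: Tuple[Timepoint, ...] = ("morning", "afternoon")

    baseline_bm_mean_kg: Dict[Sex, float] = Field(
        default_factory=lambda: {"M": 81.0, "F": 68.8}
    )
    baseline_bm_sd_kg: Dict[Sex, float] = Field(
        default_factory=lambda: {"M": 15.9, "F": 15.2}
    )

    p_dehydrated: Dict[str, Dict[str, float]] = Field(
        default_factory=_default_p_dehydrated
    )
    latent_deficit_scale: float = Field(default=1.0, ge=0.0)
    latent_noise_sd: float = Field(default=0.25, ge=0.0)
    marker_anchor: Dict[str, float] = Field(default_factory=_default_marker_anchor)
    marker_slope: Dict[str, float] = Field(default_factory=_default_marker_slope)
    marker_noise_sd: Dict[str, float] = Field(
        default_factory=_default_marker_noise_sd
    )
    bm_measurement_noise_kg: float = Field(default=0.1, ge=0.0)

    missing_plasma_counts: Dict[str, Dict[str, int]] = Field(
        default_factory=_default_missing_plasma
    )

    euh_usg_screen: float = 1.020  # EUH visits are resampled until usg < this
    rng_seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for cond, by_tp in self.p_dehydrated.items():
            if cond not in self.conditions:
                raise ConfigError(f"p_dehydrated: unknown condition {cond!r}")
            for tp, p in by_tp.items():
                if tp not in self.timepoints:
                    raise ConfigError(f"p_dehydrated: unknown timepoint {tp!r}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"p_dehydrated[{cond}][{tp}] must be in [0, 1], got {p}"
                    )
        for cond in self.conditions:
            for tp in self.timepoints:
                if self.p_dehydrated.get(cond, {}).get(tp) is None:
                    raise ConfigError(f"p_dehydrated missing entry [{cond}][{tp}]")
        for name, table in (
            ("marker_anchor", self.marker_anchor),
            ("marker_slope", self.marker_slope),
            ("marker_noise_sd", self.marker_noise_sd),
        ):
            missing = set(MARKERS) - set(table)
            if missing:
                raise ConfigError(f"{name} missing markers: {sorted(missing)}")
        for m, sd in self.marker_noise_sd.items():
            if sd < 0:
                raise ConfigError(f"marker_noise_sd[{m}] must be >= 0, got {sd}")
        for sex in ("M", "F"):
            if self.baseline_bm_mean_kg.get(sex, 0.0) <= 0:
                raise ConfigError(f"baseline_bm_mean_kg[{sex}] must be > 0")
            if self.baseline_bm_sd_kg.get(sex, -1.0) < 0:
                raise ConfigError(f"baseline_bm_sd_kg[{sex}] must be >= 0")
        n_missing = sum(
            c for by_tp in self.missing_plasma_counts.values() for c in by_tp.values()
        )
        if any(
            c < 0
            for by_tp in self.missing_plasma_counts.values()
            for c in by_tp.values()
        ):
            raise ConfigError("missing_plasma_counts entries must be >= 0")
        if n_missing > self.n_visits:
            raise ConfigError(
                "missing_plasma_counts total exceeds the number of visits "
                f"({n_missing} > {self.n_visits})"
            )
        return self

    @property
    def n_visits(self) -> int:
        """Closed-form visit count of the design grid."""
        return (
            self.n_subjects
            * len(self.conditions)
            * self.n_days_per_condition
            * len(self.timepoints)
        )

    def stratum_size(self) -> int:
        """Number of visits in each (condition, timepoint) stratum."""
        return self.n_subjects * self.n_days_per_condition


def strong_signal_config(
    n_subjects: int = 48, rng_seed: int = 0, **overrides
) -> SimConfig:
    """A cohort configuration with strong latent-marker coupling.

    Marker shifts are at least two noise standard deviations, so the latent
    dehydration state separates every marker cleanly.  Used for
    parameter-recovery checks of the accuracy pipeline.
    """
    defaults = dict(
        n_subjects=n_subjects,
        latent_deficit_scale=1.0,
        latent_noise_sd=0.12,
        marker_noise_sd={
            "bml_pct": 0.25,
            "usg": 0.003,
            "u_osm": 100.0,
            "p_osm": 2.5,
            "u_col": 0.8,
            "thirst": 0.8,
        },
        rng_seed=rng_seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def config_hash(model: BaseModel) -> str:
    """Short stable hash of a configuration, for run logging."""
    payload = json.dumps(model.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
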