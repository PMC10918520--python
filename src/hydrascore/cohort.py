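"""Synthetic hydration cohort generator.

Emulates a repeated-measures spot-sample study: each subject is observed
morning and afternoon on three consecutive days under free living (FL) and
again under enforced euhydration (EUH).  A latent binary dehydration state
per visit drives all six markers monotonically — body mass down, urine
colour, thirst, urine specific gravity and both osmolalities up — so the
cross-marker correlation the downstream accuracy analysis assumes is built
in structurally.  EUH visits are rejection-sampled until the spot USG
satisfies the euhydration screen (USG < 1.020), mirroring how the enforced
condition is verified in practice.  Plasma osmolality can then be knocked
out for a fixed number of visits per (condition, timepoint) stratum to
emulate stratified sample loss.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import MARKERS, SimConfig, config_hash

logger = logging.getLogger("hydrascore")

#: Column order of a simulated cohort frame (truth columns last).
VISIT_COLUMNS = [
    "subject_id",
    "sex",
    "condition",
    "day",
    "timepoint",
    "body_mass_kg",
    "u_col",
    "thirst",
    "usg",
    "u_osm",
    "p_osm",
]
TRUTH_COLUMNS = ["latent_dehydrated", "latent_deficit"]

_MAX_REJECTIONS = 100_000


def _draw_visit(
    rng: np.random.Generator, config: SimConfig, baseline_bm: float, p_deh: float
) -> dict:
    """One latent state + marker panel draw (no euhydration screen)."""
    d = bool(rng.random() < p_deh)
    z = config.latent_deficit_scale * d + rng.normal(0.0, config.latent_noise_sd)

    raw = {
        m: config.marker_anchor[m]
        + config.marker_slope[m] * z
        + rng.normal(0.0, config.marker_noise_sd[m])
        for m in MARKERS
    }
    body_mass = baseline_bm * (1.0 - raw["bml_pct"] / 100.0) + rng.normal(
        0.0, config.bm_measurement_noise_kg
    )
    return {
        "body_mass_kg": round(max(body_mass, 1.0), 2),
        "u_col": int(np.clip(round(raw["u_col"]), 1, 8)),
        "thirst": int(np.clip(round(raw["thirst"]), 1, 9)),
        "usg": round(float(np.clip(raw["usg"], 1.000, 1.040)), 3),
        "u_osm": float(int(np.clip(round(raw["u_osm"]), 50, 1500))),
        "p_osm": float(int(np.clip(round(raw["p_osm"]), 250, 330))),
        "latent_dehydrated": d,
        "latent_deficit": float(z),
    }


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate one visit row per (subject, condition, day, timepoint).

    Returns a long-format frame with the marker panel plus the latent truth
    columns ``latent_dehydrated`` and ``latent_deficit``.  Deterministic
    given ``config.rng_seed``.  EUH visits are redrawn until
    ``usg < config.euh_usg_screen``.
    """
    logger.info(
        "simulate_cohort: seed=%d config_hash=%s", config.rng_seed, config_hash(config)
    )
    rng = np.random.default_rng(config.rng_seed)
    width = max(2, len(str(config.n_subjects)))
    n_male = config.n_subjects // 2

    rows = []
    for i in range(config.n_subjects):
        sex = "M" if i < n_male else "F"
        baseline = rng.normal(
            config.baseline_bm_mean_kg[sex], config.baseline_bm_sd_kg[sex]
        )
        baseline = max(baseline, 40.0)  # keep body mass physiological
        subject_id = f"S{i + 1:0{width}d}"
        for condition in config.conditions:
            for day in range(1, config.n_days_per_condition + 1):
                for timepoint in config.timepoints:
                    p_deh = config.p_dehydrated[condition][timepoint]
                    for attempt in range(_MAX_REJECTIONS):
                        draw = _draw_visit(rng, config, baseline, p_deh)
                        if condition != "EUH" or draw["usg"] < config.euh_usg_screen:
                            break
                    else:
                        raise RuntimeError(
                            "euhydration screen rejected every draw; "
                            "check usg anchor/slope against euh_usg_screen"
                        )
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "sex": sex,
                            "condition": condition,
                            "day": day,
                            "timepoint": timepoint,
                            **draw,
                        }
                    )

    df = pd.DataFrame(rows, columns=VISIT_COLUMNS + TRUTH_COLUMNS)
    assert len(df) == config.n_visits
    return df


def inject_missingness(records: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Set ``p_osm`` to missing for a fixed count of visits per stratum.

    Selection is uniform without replacement within each
    (condition, timepoint) stratum, on an RNG stream derived from
    ``config.rng_seed`` so that marker generation and knockout selection
    are independently reproducible.  All other fields are untouched.
    """
    rng = np.random.default_rng([config.rng_seed, 104729])
    out = records.copy()
    for condition, by_tp in config.missing_plasma_counts.items():
        for timepoint, n_missing in by_tp.items():
            if n_missing == 0:
                continue
            mask = (out["condition"] == condition) & (out["timepoint"] == timepoint)
            idx = out.index[mask]
            if n_missing > len(idx):
                raise ValueError(
                    f"missing_plasma_counts[{condition}][{timepoint}] = "
                    f"{n_missing} exceeds stratum size {len(idx)}"
                )
            chosen = rng.choice(idx.to_numpy(), size=n_missing, replace=False)
            out.loc[chosen, "p_osm"] = np.nan
    return out


def simulate(config: SimConfig | None = None) -> pd.DataFrame:
    """Simulate a cohort and apply the configured plasma-sample knockout."""
    config = config or SimConfig()
    return inject_missingness(simulate_cohort(config), config)
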