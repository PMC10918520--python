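import numpy as np
import pandas as pd
import pytest

from hydrascore import SimConfig, simulate, strong_signal_config


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Reference-design cohort (24 x 2 x 3 x 2) with plasma knockout."""
    return simulate(SimConfig(rng_seed=11))


@pytest.fixture(scope="session")
def strong_cohort() -> pd.DataFrame:
    """Large cohort with strong latent-marker coupling (576 visits)."""
    return simulate(strong_signal_config(rng_seed=3))


@pytest.fixture()
def zero_noise_config() -> SimConfig:
    """No latent signal and no noise anywhere: markers frozen per subject."""
    return SimConfig(
        latent_deficit_scale=0.0,
        latent_noise_sd=0.0,
        marker_noise_sd={m: 0.0 for m in
                         ("bml_pct", "usg", "u_osm", "p_osm", "u_col", "thirst")},
        bm_measurement_noise_kg=0.0,
        rng_seed=5,
    )


def random_scored_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A minimal scored+classified frame with random counts and calls.

    Used by brute-force oracle tests; includes occasional missing plasma
    reference calls.
    """
    ref_posm = rng.choice([True, False, None], size=n, p=[0.4, 0.4, 0.2])
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "condition": rng.choice(["FL", "EUH"], size=n),
            "timepoint": rng.choice(["morning", "afternoon"], size=n),
            "wut_count": rng.integers(0, 4, size=n),
            "ref_USG": pd.array(rng.random(n) < 0.5, dtype="boolean"),
            "ref_UOSM": pd.array(rng.random(n) < 0.5, dtype="boolean"),
            "ref_POSM": pd.array(ref_posm, dtype="boolean"),
        }
    )
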