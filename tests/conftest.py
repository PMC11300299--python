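import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from smnas import CohortConfig, load_instrument


@pytest.fixture(scope="session")
def instr():
    return load_instrument()


@pytest.fixture(scope="session")
def planted_cohort():
    """Noise-free planted-mapping cohort plus its metrics table."""
    from smnas import build_metrics_table, generate_planted_mapping_cohort

    # decay_h compressed so each infant's episode completes (returns to
    # baseline) within the follow-up and all indicator classes are populated
    cfg = CohortConfig(
        n_infants=20, seed=11, follow_up_h=250, decay_h=60.0,
        mode="planted_mapping", epsilon=0.0,
    )
    scores = generate_planted_mapping_cohort(cfg)
    return scores, build_metrics_table(scores)


def make_scores(infant, times, full, short=None):
    """Minimal score table for one infant (short defaults to full // 2)."""
    full = list(full)
    if short is None:
        short = [f // 2 for f in full]
    return pd.DataFrame(
        {
            "infant_id": infant,
            "timestamp_h": list(times),
            "full_score": full,
            "short_score": list(short),
        }
    )
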