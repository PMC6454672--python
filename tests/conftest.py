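import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from strokescreen import FACTORS, CohortConfig, load_reference_tables
from strokescreen.factors import COHORT_COLUMNS


def make_cohort(factor_matrix, strokes, center_id="east_u_c00", district="east",
                urban=True, **flags):
    """Build a full-schema cohort DataFrame from a 0/1 factor matrix and outcomes."""
    X = np.asarray(factor_matrix, dtype=bool)
    strokes = np.asarray(strokes, dtype=bool)
    n = len(X)
    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "center_id": center_id if np.isscalar(center_id) else center_id,
            "district": district,
            "urban": urban,
            "age": 50,
            **{f: X[:, j] for j, f in enumerate(FACTORS)},
            "prior_stroke": flags.get("prior_stroke", False),
            "incident_stroke": strokes,
            "stroke_subtype": np.where(strokes, "cerebral_infarction", "none"),
            "lost_to_followup": flags.get("lost_to_followup", False),
            "data_error": flags.get("data_error", False),
        },
        columns=list(COHORT_COLUMNS),
    )
    return df


def random_cohort(rng, n=20, stroke_rate=0.3):
    """Random small cohort for brute-force oracle comparisons."""
    X = rng.random((n, 8)) < rng.random(8)
    strokes = rng.random(n) < stroke_rate
    return make_cohort(X, strokes)


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture
def clean_config():
    """A small generator config with no exclusion flags, for recovery checks."""
    return CohortConfig(
        n_people=20000,
        prior_stroke_rate=0.0,
        lost_followup_rate=0.0,
        error_rate=0.0,
        seed=42,
    )
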