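import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import polytome as pt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort() -> pt.SyntheticCohort:
    """The generator's default study-scale cohort (counts only)."""
    return pt.simulate_cohort(seed=1, with_sequences=False)


@pytest.fixture(scope="session")
def small_cohort() -> pt.SyntheticCohort:
    """A small, fully sequenced cohort for end-to-end and IO tests."""
    cluster_specs = tuple(
        pt.ClusterSpec(s.cluster_id, max(6, s.n_genes // 10), s.delta)
        for s in pt.DEFAULT_CLUSTER_SPECS
    )
    spec = pt.TranscriptSpec(
        utr5_len_median=80.0,
        cds_codons_median=60.0,
        utr3_len_median=100.0,
        utr3_len_log_sd=0.3,
    )
    cfg = pt.SimulationConfig(
        n_genes=400,
        cluster_specs=cluster_specs,
        transcript_spec=spec,
        seed=7,
    )
    return pt.simulate_counts(cfg)


@pytest.fixture()
def toy_counts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A hand-sized counts table with a matching sample sheet (2 fractions)."""
    rng = np.random.default_rng(0)
    sheet = pd.DataFrame(
        {
            "sample_id": [f"{f}_{c}_{r}" for f in ("total", "heavy") for c in ("low", "high") for r in (1, 2, 3)],
            "condition": [c for f in ("total", "heavy") for c in ("low", "high") for r in (1, 2, 3)],
            "fraction": [f for f in ("total", "heavy") for c in ("low", "high") for r in (1, 2, 3)],
            "replicate": [r for f in ("total", "heavy") for c in ("low", "high") for r in (1, 2, 3)],
        }
    )
    counts = pd.DataFrame(
        rng.poisson(100, (50, len(sheet))),
        index=[f"g{i:02d}" for i in range(50)],
        columns=list(sheet["sample_id"]),
    )
    return counts, sheet
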