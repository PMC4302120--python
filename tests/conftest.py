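import numpy as np
import pandas as pd
import pytest

from twinewas import GeneratorConfig, generate_cohort, generate_methylation
from twinewas.containers import TwinCohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale dataset exercising every planted feature."""
    return GeneratorConfig(
        n_pairs=60, n_probes=800, seed=3, n_reference_probes=80,
        n_failing_probes=5, n_high_missing_probes=5,
        frac_causal_alpha=0.02, frac_causal_dbw=0.02, frac_causal_age=0.02,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    cohort = generate_cohort(small_config)
    beta, M, U, detp, truth = generate_methylation(cohort, small_config)
    return {"cohort": cohort, "beta": beta, "M": M, "U": U, "detp": detp, "truth": truth}


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (150 pairs), demography only."""
    return generate_cohort(GeneratorConfig(n_pairs=150, n_probes=100, seed=0))


def make_cohort_frame(records):
    """Build a cohort frame from (pair_id, bw_big, bw_small, age, sex, ga) tuples."""
    rows = []
    for i, (pid, bb, bs, age, sex, ga) in enumerate(records):
        common = dict(pair_id=pid, age=age, sex=sex, birth_year=2009 - age,
                      gestational_age=ga, plate=f"P{i // 6 + 1:02d}", well=f"W{i % 6 + 1}",
                      sentrix_position=f"R{i % 6 + 1:02d}C01", is_replicate_of=None)
        rows.append(dict(sample_id=f"{pid}_B", twin_role="bigger", birth_weight=bb, **common))
        rows.append(dict(sample_id=f"{pid}_S", twin_role="smaller", birth_weight=bs, **common))
    df = pd.DataFrame(rows)
    df["is_replicate_of"] = df["is_replicate_of"].astype(object)
    return df


@pytest.fixture
def tiny_cohort():
    return TwinCohort(make_cohort_frame([
        ("p1", 2000.0, 1500.0, 33, "male", 39.0),
        ("p2", 3000.0, 2700.0, 60, "female", np.nan),
        ("p3", 1700.0, 900.0, 35, "female", 36.0),
        ("p4", 2500.0, 2300.0, 62, "male", np.nan),
    ]))
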