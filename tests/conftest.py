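import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from irgp.data_io import ClinicalTable, ExpressionMatrix
from irgp.synthetic_data import SimConfig, gene_names, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with distinct values (no ties)."""
    data = pd.DataFrame(
        {
            "S1": [5.0, 3.0, 1.0],
            "S2": [2.0, 4.0, 6.0],
            "S3": [7.0, 1.0, 2.0],
            "S4": [0.5, 0.9, 0.7],
        },
        index=["A", "B", "C"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_clinical() -> ClinicalTable:
    data = pd.DataFrame(
        {
            "time": [10.0, 20.0, 15.0, 30.0],
            "event": [1, 0, 1, 1],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return ClinicalTable(data, time_unit="months")


@pytest.fixture(scope="session")
def planted_cohort():
    """n=300 cohort with two planted pairs (log-HR +1 / -1) among 50 noise pairs."""
    genes = gene_names(104)
    planted = (((genes[0], genes[1]), 1.0), ((genes[2], genes[3]), -1.0))
    cfg = SimConfig(n_samples=300, n_genes=104, planted_pairs=planted, seed=11)
    cohort = simulate_cohort(cfg)
    noise_pairs = [(genes[i], genes[i + 1]) for i in range(4, 104, 2)]
    return cohort, planted, noise_pairs


@pytest.fixture(scope="session")
def null_cohort():
    """n=500 cohort with no planted effects."""
    return simulate_cohort(SimConfig(n_samples=500, n_genes=20, seed=23))


def mh_logrank_oracle(time, event, group):
    """Independent Mantel-Haenszel log-rank chi-square (direct summation)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    obs = exp = var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var if var > 0 else 0.0
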