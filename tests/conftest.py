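import numpy as np
import pandas as pd
import pytest

from cortexlv import assembly, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort shared by read-only tests."""
    cfg = synthetic.CohortConfig(
        n_vertices=300, n_subjects=80, k_true=4, n_lv=2, noise_sd=0.05
    )
    return synthetic.simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Full desk-scale cohort (2000 vertices, 400 subjects, k_true=10)."""
    return synthetic.simulate_cohort(synthetic.CohortConfig(), seed=1)


@pytest.fixture(scope="session")
def default_stacked(default_cohort):
    tables = [default_cohort.metric_tables[m] for m in assembly.METRICS]
    return assembly.assemble(tables)


def true_cognition_matrix(truth) -> pd.DataFrame:
    """Cognition matrix built from the generator's planted coefficients."""
    cols = {}
    for t in synthetic.TESTS:
        cols[f"{t}_intercept"] = truth.true_intercepts[t]
        cols[f"{t}_slope"] = truth.true_slopes[t]
    return pd.DataFrame(cols, index=truth.subject_ids)


@pytest.fixture(scope="session")
def planted_pls_blocks(default_cohort):
    """(X, Y, truth) with the planted brain weights and coefficients."""
    truth = default_cohort.truth
    return truth.brain_weights, true_cognition_matrix(truth), truth


def make_metric(values, metric="CT", scanners=None, mask=None):
    values = np.asarray(values, dtype=float)
    n_v, n_s = values.shape
    return assembly.VertexMetricMatrix(
        metric_name=metric,
        values=values,
        subject_ids=[f"s{i}" for i in range(n_s)],
        scanner_labels=scanners or ["A"] * n_s,
        mask=mask if mask is not None else np.arange(n_v),
    )
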