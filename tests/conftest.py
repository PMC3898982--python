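import numpy as np
import pandas as pd
import pytest

import ccpmeta as cm


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-sample cohort with strong proliferation signal and survival
    endpoint, shared across read-only tests."""
    spec = cm.CohortSpec(n_samples=150, n_genes=200, beta_prolif=1.0,
                         beta_indep=1.0, baseline_hazard=0.1, censor_max=20.0,
                         seed=11)
    return cm.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return cm.znormalize(cm.collapse_probes(small_cohort.expression))


@pytest.fixture()
def surv_clin():
    """Tiny hand-written survival table."""
    rng = np.random.default_rng(5)
    n = 40
    data = pd.DataFrame({
        "time": rng.exponential(5.0, n),
        "event": rng.integers(0, 2, n),
        "age": rng.normal(60, 8, n),
    }, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
    data.loc[data.index[:4], "event"] = 1
    return cm.ClinicalTable(endpoint_kind="OS", data=data)


def score_vector(values, ids=None, name="score"):
    values = np.asarray(values, dtype=float)
    ids = pd.Index(ids if ids is not None else [f"S{i}" for i in range(len(values))])
    return cm.ScoreVector(sample_ids=ids, score=values, n_genes_used=1,
                          coverage=1.0, name=name)
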