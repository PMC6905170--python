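import numpy as np
import pandas as pd
import pytest

from methclock.core_io import BetaMatrix
from methclock.synthetic import SimConfig, TumorCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort: normals + one shifted tumor cohort."""
    cfg = SimConfig(
        n_sites=400,
        n_clock_sites=60,
        n_normal=120,
        tumor_cohorts=[TumorCohortSpec("TUMA", 60, -10.0, 2.0)],
        n_diff_sites=10,
        n_risk_sites=3,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def normal_view(small_cohort):
    """(matrix restricted to normals, ages aligned to its columns)."""
    matrix, annotations, _ = small_cohort
    ids = [a.sample_id for a in annotations if a.condition == "normal"]
    ages = pd.Series(
        {a.sample_id: a.age_years for a in annotations if a.condition == "normal"}
    )
    return matrix.restrict_samples(ids), ages[ids]


def make_matrix(values, site_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    site_ids = site_ids or [f"cg{i:08d}" for i in range(m)]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(n)]
    df = pd.DataFrame(values, index=site_ids, columns=sample_ids)
    df.index.name = "site_id"
    return BetaMatrix(df)
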