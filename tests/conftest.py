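import numpy as np
import pandas as pd
import pytest

from pgkit.io import OmicsMatrix
from pgkit.synthetic import CohortConfig, generate_cohort


SMALL_CONFIG = dict(n_patients=60, n_genes=400, n_phosphosites=160,
                    program_size=50, n_cis_genes=30, n_subtype_markers=8,
                    n_mut_per_sample=40, n_null_kinases=10, rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate paired cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def tumor_nat_ids(small_cohort):
    cols = small_cohort.layers["protein"].values.columns
    return ([s for s in cols if s.endswith("_T")],
            [s for s in cols if s.endswith("_N")])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, layer="protein", scale="log2", features=None,
                samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=features, columns=samples),
                       layer=layer, scale=scale)
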