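import numpy as np
import pandas as pd
import pytest

from steatomir import CohortConfig, CountMatrix, NormalizedMatrix, PhenotypeVector, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest paired cohort used by several integration-level tests."""
    cfg = CohortConfig(n_mirna=60, n_informative=10, effect_size=1.5, seed=42)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_counts(values, mirna_ids=None, sample_ids=None) -> CountMatrix:
    values = np.asarray(values)
    mirna_ids = mirna_ids or [f"hsa-miR-{100+i}-5p" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=mirna_ids, columns=sample_ids))


def make_normalized(values, mirna_ids=None, sample_ids=None) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    mirna_ids = mirna_ids or [f"hsa-miR-{100+i}-5p" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=mirna_ids, columns=sample_ids)
    return NormalizedMatrix(df, pd.Series(1.0, index=df.columns))


def make_phenotype(values, sample_ids=None, unit="") -> PhenotypeVector:
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"S{j}" for j in range(len(values))]
    return PhenotypeVector(pd.Series(values, index=sample_ids), unit=unit)
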