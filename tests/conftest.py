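import numpy as np
import pandas as pd
import pytest

from metareduce import METAL, SimulationConfig, SumstatsTable
from metareduce.io import empty_frame


def make_table(rows, source_label="test", dialect=METAL):
    """Build a SumstatsTable from dicts with canonical field names."""
    if not rows:
        return SumstatsTable(df=empty_frame(), source_label=source_label, dialect=dialect)
    df = pd.DataFrame(rows)
    for col in ("effect_allele", "other_allele", "pvalue", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[["marker_id", "effect_allele", "other_allele", "beta", "se", "pvalue", "n"]]
    return SumstatsTable(df=df, source_label=source_label, dialect=dialect)


@pytest.fixture
def three_cohort_tables():
    """Three one-marker cohorts with equal se: pooled B=0.2, SE^2=1/300."""
    return [
        make_table([{"marker_id": "rs1", "effect_allele": "A", "other_allele": "G",
                     "beta": b, "se": 0.1}], source_label=f"c{i}")
        for i, b in enumerate((0.1, 0.2, 0.3))
    ]


@pytest.fixture
def small_config():
    return SimulationConfig(K=4, M=500, n_per_cohort=(20_000, 8_000, 45_000, 6_000), seed=11)
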