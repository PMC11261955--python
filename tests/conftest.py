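import numpy as np
import pandas as pd
import pytest

from thyrodissect.sumstats import SummaryStatsTable, pval_from_chisq


def make_table(rows, cohort="test"):
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "af", "beta", "se", "pval"]
    )
    return SummaryStatsTable(df, cohort=cohort)


@pytest.fixture
def small_table():
    return make_table(
        [
            ("1", 1000, "A", "G", 0.30, 0.10, 0.02, pval_from_chisq(25.0)),
            ("1", 5000, "C", "T", 0.10, -0.20, 0.04, pval_from_chisq(25.0)),
            ("2", 1000, "G", "A", 0.45, 0.05, 0.02, pval_from_chisq(6.25)),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240708)
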