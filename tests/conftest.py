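import numpy as np
import pandas as pd
import pytest

from methylrelease import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A default synthetic screen cohort (76 samples, planted signature)."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture()
def toy_beta():
    """3 samples x 4 probes beta matrix with one missing entry."""
    return pd.DataFrame(
        [[0.1, 0.5, 0.9, 0.3], [0.2, np.nan, 0.8, 0.4], [0.15, 0.55, 0.85, 0.35]],
        index=["s1", "s2", "s3"],
        columns=["cg1", "cg2", "cg3", "cg4"],
    )


@pytest.fixture()
def toy_annotation():
    return pd.DataFrame(
        {
            "probe_id": ["cg1", "cg2", "cg3", "cg4"],
            "chrom": ["chr1", "chr2", "chrX", "chr3"],
            "pos": [100, 200, 300, 400],
            "cross_reactive": [False, False, False, False],
            "snp_at_target": [False, False, False, False],
            "gene": ["A", "B", "C", "D"],
            "is_promoter": [True, False, False, True],
        }
    )
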