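import numpy as np
import pandas as pd
import pytest

import transtype as tt


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the package's default study conditions."""
    cfg = tt.SimConfig(seed=1)
    matrices, annotation, truth = tt.simulate_cohort(cfg)
    return cfg, matrices, annotation, truth


@pytest.fixture(scope="session")
def mrna_cohort():
    """mRNA-only cohort with no samples missing, for clustering tests."""
    cfg = tt.SimConfig(
        seed=1, missing_platform_prob=0.0, features_per_platform={"mrna": 500}
    )
    matrices, annotation, truth = tt.simulate_cohort(cfg)
    return matrices["mrna"], truth


def make_matrix(values, platform="mrna", lineage=None, features=None, samples=None,
                normalized=False):
    """Small OmicsMatrix helper for hand-built fixtures."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"g{i + 1}" for i in range(n_feat)]
    samples = samples or [f"s{j + 1}" for j in range(n_samp)]
    if lineage is None:
        lineage = {s: "all" for s in samples}
    df = pd.DataFrame(values, index=features, columns=samples)
    return tt.OmicsMatrix(platform, df, pd.Series(lineage), normalized=normalized)
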