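"""Shared fixtures: small synthetic data built programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

from capmeth import synthetic as sd
from capmeth.types import CountMatrix


@pytest.fixture(scope="session")
def truth_small():
    return sd.generate_ground_truth(200, "starvation", seed=11)


@pytest.fixture(scope="session")
def sim_small(truth_small):
    cfg = sd.AssayConfig(depth=3e5, n_replicates=2, seed=11)
    return sd.simulate_libraries(truth_small, cfg)


@pytest.fixture(scope="session")
def noiseless():
    """Noise-free expected counts with ideal chemistry (zero IP background,
    fully methylated rich medium), the closed-form estimator oracle."""
    params = sd.GroundTruthParams(rich_range=(1.0, 1.0))
    truth = sd.generate_ground_truth(150, "starvation", seed=5, params=params)
    cfg = sd.AssayConfig(beta_ip=0.0, depth=1e6, dispersion=0.0, n_replicates=2)
    return truth, cfg, sd.expected_libraries(truth, cfg)


def toy_ip_matrix(ratios_rich, ratios_min, input_count=1000, spike=10_000):
    """Hand-built two-condition IP matrix with one replicate.

    ``ratios_*`` map gene id -> desired IP/input ratio; every library
    gets one ERCC row with an equal spike total so normalization is the
    identity up to the common factor.
    """
    genes = list(ratios_rich)
    cols = {}
    for cond, ratios in (("rich", ratios_rich), ("min", ratios_min)):
        cols[f"ip_{cond}_input_1"] = [input_count] * len(genes) + [spike]
        cols[f"ip_{cond}_ip_1"] = [int(round(input_count * ratios[g])) for g in genes] + [spike]
    counts = pd.DataFrame(cols, index=pd.Index(genes + ["ERCC-00001"], name="gene_id"))
    meta = pd.DataFrame.from_dict(
        {
            sid: dict(
                assay="ip",
                condition=sid.split("_")[1],
                fraction=sid.split("_")[2],
                replicate=1,
            )
            for sid in cols
        },
        orient="index",
    )
    meta.index.name = "sample_id"
    spike_flag = pd.Series([False] * len(genes) + [True], index=counts.index)
    return CountMatrix(counts, meta, spike_flag)
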