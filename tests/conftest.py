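import numpy as np
import pandas as pd
import pytest

import rankmarkers as rm


@pytest.fixture(scope="session")
def panel_run():
    """A default simulated digital-count run (42 tumor, 3 normal, outlier)."""
    return rm.generate_nanostring_run(rm.PanelSimConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_run(panel_run):
    return rm.normalize_housekeeping(panel_run.raw_counts, panel_run.hk_genes)


@pytest.fixture(scope="session")
def small_discovery():
    """Small discovery cohorts with 10 planted genes (seed 7)."""
    cfg = rm.DiscoverySimConfig(
        n_genes_common=200,
        n_genes_extra_a=30,
        n_genes_extra_b=50,
        n_tumor_samples=25,
        n_normal_samples=15,
        n_planted=10,
        seed=7,
    )
    return rm.generate_discovery_cohorts(cfg)


def make_matrix(values, genes=None, samples=None, unit="raw-count", labels=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return rm.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        unit_label=unit,
        sample_labels=labels,
    )
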