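import numpy as np
import pandas as pd
import pytest

from glycotma import annotation_registry as ar
from glycotma import cohort_stats as cs
from glycotma import synthetic_cohort as sc


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three-patient cohort with geometry, small enough for e2e tests."""
    cfg = sc.CohortConfig(seed=11, n_patients=3,
                          distant_sites=("bone", "rib", "liver"))
    return sc.generate_cohort(cfg, geometry=True)


@pytest.fixture(scope="session")
def planted_cohort():
    """Full-size cohort with a clean planted metastasis effect
    (every patient trend-consistent), no geometry."""
    cfg = sc.CohortConfig(seed=5, consistent_fraction=1.0)
    return sc.generate_cohort(cfg, geometry=False)


@pytest.fixture(scope="session")
def planted_agg(planted_cohort):
    attrs = ar.pool_bone_sites(planted_cohort.attrs)
    agg, _ = cs.aggregate(attrs, planted_cohort.dataset)
    return agg


def make_agg(rows):
    """Aggregate-table helper for hand-constructed statistics tests.

    rows: iterable of (tma_id, tissue_site, category, channel,
    mean_intensity, n_pixels)."""
    return pd.DataFrame(rows, columns=[
        "tma_id", "tissue_site", "category", "channel",
        "mean_intensity", "n_pixels"])
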