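import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gnurture import scores, simfam, transmission

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """50 families, 2 chromosomes x 600 markers, mix of pairs and trios."""
    return simfam.simulate_dataset(
        n_families=50,
        n_chromosomes=2,
        markers_per_chromosome=600,
        length_cm=100.0,
        pair_fraction=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_tmap(small_dataset):
    return transmission.infer_all(small_dataset.haps, small_dataset.pedigree)


@pytest.fixture(scope="session")
def analysis_frame():
    """Score-level generated analysis frame with standardized score columns."""
    df = simfam.simulate_analysis_table(2000, simfam.PhenoModelParams(), seed=9)
    df = scores.residualize_standardize(
        df, ["pgs_t", "pgs_nt", "mt", "pt", "mnt", "pnt"]
    )
    return df


def zscore(x):
    x = np.asarray(x, float)
    return (x - np.nanmean(x)) / np.nanstd(x)
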