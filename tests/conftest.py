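import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ssipscore as ss
from ssipscore import datasets

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort_counts():
    return datasets.load_cohort_allele_counts()


@pytest.fixture(scope="session")
def tv_results(cohort_counts):
    return ss.compare_allele_frequencies(cohort_counts, "TurkishVariome")


@pytest.fixture(scope="session")
def gnomad_results(cohort_counts):
    return ss.compare_allele_frequencies(cohort_counts, "gnomAD")


@pytest.fixture(scope="session")
def cohort_af_all(tv_results, gnomad_results):
    return pd.concat([gnomad_results, tv_results], ignore_index=True)


@pytest.fixture
def small_synth():
    """Reduced-scale synthetic matrix for fast unit tests."""
    cfg = ss.SynthConfig(n_pathogenic=6, n_benign=6, n_vus=60,
                         n_informative=4, n_noise=4, seed=7)
    return ss.generate_score_matrix(cfg)
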