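import numpy as np
import pytest
from hypothesis import settings

from bonecheck.synth import (
    CohortConfig,
    AnomalyCounts,
    make_species_panels,
    sample_reference_panel,
    simulate_cohort,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panels():
    """Lion/tiger frequency panels at the default study conditions."""
    lion, tiger, snp_defs = make_species_panels(18, (5, 11), 0.8, seed=0)
    return lion, tiger, snp_defs


@pytest.fixture(scope="session")
def ref_panels(panels):
    """20+20 reference genotypes drawn from the panels."""
    lion, tiger, _ = panels
    rng = np.random.default_rng(1)
    return sample_reference_panel(lion, 20, rng), sample_reference_panel(tiger, 20, rng)


@pytest.fixture(scope="session")
def small_scenario(panels):
    """A reduced quota with one planted anomaly of each class."""
    lion, tiger, _ = panels
    config = CohortConfig(
        quota_size=120,
        spot_fraction=0.25,
        n_facilities=3,
        consignment_size=20,
        anomalies=AnomalyCounts(
            non_target_species=1,
            reassigned_tag=1,
            pooled_no_match=1,
            duplicate_individual=1,
        ),
        seed=11,
    )
    farm, port, truth = simulate_cohort(config, (lion, tiger))
    return config, farm, port, truth
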