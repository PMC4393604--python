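import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bzipkit import domain_scan, synth  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """60 proteins with ground truth (shared across read-only tests)."""
    spec = synth.CohortSpec(n_proteins=60)
    records, truths = synth.gen_protein_cohort(spec, seed=101)
    return spec, records, truths


@pytest.fixture(scope="session")
def scanned_cohort(small_cohort):
    spec, records, truths = small_cohort
    scanned = [domain_scan.scan_protein(r) for r in records]
    return spec, records, truths, scanned


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
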