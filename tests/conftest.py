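import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_null_cohort():
    """60 subjects, 20 regions, two sites, nothing planted."""
    from fcpipe import SimulationConfig, SiteSpec, generate_cohort

    sites = (
        SiteSpec(site_id="S1", n_asd=15, n_td=15, n_timepoints=150),
        SiteSpec(site_id="S2", n_asd=15, n_td=15, n_timepoints=150),
    )
    config = SimulationConfig(n_regions=20, sites=sites, seed=7)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def labels_and_sites():
    def _extract(cohort, subject_ids):
        from fcpipe.classification import ASD_LABEL, TD_LABEL

        by_id = {s.subject_id: s for s in cohort.subjects}
        y = np.array(
            [ASD_LABEL if by_id[s].group == "ASD" else TD_LABEL for s in subject_ids]
        )
        sites = np.array([by_id[s].site_id for s in subject_ids])
        return y, sites

    return _extract
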