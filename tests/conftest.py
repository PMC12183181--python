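import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcpipe import EdgeIndexMap, RoiTimeSeries, SyntheticDesign, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny three-group, two-site cohort used across modules."""
    design = SyntheticDesign(
        n_per_group=(6, 6, 6), n_rois=10, n_timepoints=120, n_sites=2,
        tr_seconds=2.0, seed=11,
    )
    records, series = generate_cohort(design)
    return design, records, series


@pytest.fixture
def edge_map_10():
    return EdgeIndexMap(10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_series(rng):
    """White-noise 10-ROI series with TR = 2 s."""
    return RoiTimeSeries(rng.standard_normal((120, 10)), tr_seconds=2.0, subject_id="noise")
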