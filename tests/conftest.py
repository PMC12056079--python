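import numpy as np
import pytest

from fcpair.cohort import CONDITIONS, CohortConfig, generate_roi_cohort
from fcpair.preprocess import compute_fc, run_first_level


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject ROI cohort with a distributed effect, shared across tests."""
    cfg = CohortConfig(n_subjects=6, n_frames=120, seed=42)
    return generate_roi_cohort(cfg)


def cohort_fc(cohort, discard_frames=4):
    """Preprocess every scan of a cohort into connectivity matrices."""
    fc_by = {}
    for s in cohort.subjects:
        fc_by[s.subject_id] = {}
        for cond in CONDITIONS:
            scan = cohort.scans[(s.subject_id, cond)]
            cleaned = run_first_level(scan, "roi_fc", discard_frames=discard_frames)
            fc_by[s.subject_id][cond] = compute_fc(
                cleaned, scan.channel_labels, cohort.network_of,
                cohort.hemisphere_of,
            )
    return fc_by


@pytest.fixture(scope="session")
def small_cohort_fc(small_cohort):
    return cohort_fc(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
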