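import numpy as np
import pytest

from hmmdfc import synthetic, prep
from hmmdfc.types import AtlasMapping, CohortDataset, SubjectTimeSeries


@pytest.fixture(scope="session")
def tiny_atlas() -> AtlasMapping:
    return AtlasMapping(
        roi_names=[f"R{i}" for i in range(4)],
        networks=["VN", "VN", "SMN", "SMN"])


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.test_scale_spec(master_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return synthetic.simulate_cohort(small_spec)


def make_subject(data, subject_id="s1", group="control", **kw):
    return SubjectTimeSeries(subject_id=subject_id, group=group,
                             data=np.asarray(data, float), **kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def prep_cohort(cohort: CohortDataset) -> CohortDataset:
    """QC + z-score every subject of a cohort (excluded subjects dropped)."""
    kept = []
    for s in cohort.subjects:
        res = prep.qc_and_scrub(s)
        if not res.excluded:
            kept.append(prep.zscore(res.subject))
    return CohortDataset(subjects=kept, clinical=cohort.clinical,
                         atlas=cohort.atlas)
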