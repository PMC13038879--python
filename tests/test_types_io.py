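"""Data model validation and on-disk round trips."""

import numpy as np
import pandas as pd
import pytest

from hmmdfc import io as io_mod
from hmmdfc.types import (AtlasMapping, CohortDataset, ValidationError,
                          validate_clinical)

from conftest import make_subject


class TestAtlas:
    def test_valid_and_lookup(self, tiny_atlas):
        assert tiny_atlas.n_rois == 4
        np.testing.assert_array_equal(tiny_atlas.rois_in_network("SMN"),
                                      [2, 3])

    def test_unknown_network_rejected(self):
        with pytest.raises(ValidationError, match="network"):
            AtlasMapping(roi_names=["a"], networks=["XXX"])

    def test_duplicate_roi_rejected(self):
        with pytest.raises(ValidationError):
            AtlasMapping(roi_names=["a", "a"], networks=["VN", "VN"])

    def test_noncontiguous_index_rejected(self):
        df = pd.DataFrame({"roi_index": [0, 2], "roi_name": ["a", "b"],
                           "network": ["VN", "VN"]})
        with pytest.raises(ValidationError, match="contiguous"):
            AtlasMapping.from_frame(df)


class TestSubjectTimeSeries:
    def test_segments_must_sum_to_t(self, rng):
        with pytest.raises(ValidationError, match="segments"):
            make_subject(rng.normal(size=(10, 2)), segments=[4, 4])

    def test_nan_rejected(self):
        data = np.ones((5, 2))
        data[2, 1] = np.nan
        with pytest.raises(ValidationError, match="non-finite"):
            make_subject(data)

    def test_fd_length_checked(self, rng):
        with pytest.raises(ValidationError, match="fd_trace"):
            make_subject(rng.normal(size=(5, 2)), fd_trace=np.ones(4))


def test_clinical_ranges_enforced():
    bad = pd.DataFrame({"vas": [11.0]},
                       index=pd.Index(["p1"], name="subject_id"))
    with pytest.raises(ValidationError, match="vas"):
        validate_clinical(bad)
    ok = pd.DataFrame({"vas": [np.nan], "hit6": [50.0]},
                      index=pd.Index(["p1"], name="subject_id"))
    out = validate_clinical(ok)
    assert np.isnan(out.loc["p1", "midas"])     # absent columns filled


def test_cohort_mismatched_n_names_subject(tiny_atlas, rng):
    good = make_subject(rng.normal(size=(6, 4)), subject_id="s1")
    bad = make_subject(rng.normal(size=(6, 5)), subject_id="s2")
    with pytest.raises(ValidationError, match="s2"):
        CohortDataset(subjects=[good, bad],
                      clinical=pd.DataFrame(index=pd.Index(
                          [], name="subject_id")),
                      atlas=tiny_atlas)


def test_cohort_roundtrip_exact(tmp_path, small_cohort):
    """write_cohort -> read_cohort reproduces matrices, FD, segments and
    clinical values to full stored precision."""
    cohort, _ = small_cohort
    sub = CohortDataset(subjects=cohort.subjects[:3],
                        clinical=cohort.clinical.loc[
                            [s.subject_id for s in cohort.subjects[:3]]],
                        atlas=cohort.atlas)
    manifest = io_mod.write_cohort(sub, tmp_path / "cohort")
    back = io_mod.read_cohort(manifest, tmp_path / "cohort" / "atlas.tsv")
    assert back.subject_ids == sub.subject_ids
    for a, b in zip(sub.subjects, back.subjects):
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.fd_trace, b.fd_trace)
        assert a.segments == b.segments
        assert a.group == b.group
    pd.testing.assert_frame_equal(
        sub.clinical.sort_index(), back.clinical.sort_index(),
        check_like=True)


def test_read_cohort_errors(tmp_path, small_cohort):
    cohort, _ = small_cohort
    sub = CohortDataset(subjects=cohort.subjects[:2],
                        clinical=cohort.clinical.iloc[0:0],
                        atlas=cohort.atlas)
    manifest = io_mod.write_cohort(sub, tmp_path / "c")
    # corrupt second subject's file: drop a column
    ts_path = tmp_path / "c" / "timeseries" / \
        f"{sub.subjects[1].subject_id}.tsv"
    df = pd.read_csv(ts_path, sep="\t")
    df.iloc[:, :-1].to_csv(ts_path, sep="\t", index=False)
    with pytest.raises(ValidationError, match=sub.subjects[1].subject_id):
        io_mod.read_cohort(manifest, tmp_path / "c" / "atlas.tsv")
    # unknown group label
    mf = pd.read_csv(manifest, sep="\t")
    mf.loc[0, "group"] = "sick"
    mf.to_csv(manifest, sep="\t", index=False)
    with pytest.raises(ValidationError, match="group"):
        io_mod.read_cohort(manifest, tmp_path / "c" / "atlas.tsv")


def test_missing_timeseries_file_reports_path(tmp_path, small_cohort):
    cohort, _ = small_cohort
    sub = CohortDataset(subjects=cohort.subjects[:1],
                        clinical=cohort.clinical.iloc[0:0],
                        atlas=cohort.atlas)
    manifest = io_mod.write_cohort(sub, tmp_path / "c")
    (tmp_path / "c" / "timeseries" /
     f"{sub.subjects[0].subject_id}.tsv").unlink()
    with pytest.raises(ValidationError, match="not found"):
        io_mod.read_cohort(manifest, tmp_path / "c" / "atlas.tsv")


def test_write_results_precision_and_empty(tmp_path):
    tables = {
        "stats": pd.DataFrame({"edge": ["1-2"], "q": [1.39e-13]}),
        "empty": pd.DataFrame(columns=["a", "b"]),
    }
    io_mod.write_results(tables, tmp_path, run_info={"seed": 1})
    back = pd.read_csv(tmp_path / "stats.tsv", sep="\t")
    assert back["q"].iloc[0] == 1.39e-13        # survives round-trip
    empty = pd.read_csv(tmp_path / "empty.tsv", sep="\t")
    assert list(empty.columns) == ["a", "b"] and empty.empty
    assert (tmp_path / "run_manifest.json").exists()


def test_matrix_roundtrip(tmp_path, rng):
    m = rng.normal(size=(5, 5))
    io_mod.write_matrix(m, tmp_path / "m.tsv")
    np.testing.assert_array_equal(io_mod.read_matrix(tmp_path / "m.tsv"),
                                  m)
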