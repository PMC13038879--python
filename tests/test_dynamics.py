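"""Temporal state metrics against a brute-force run-length oracle."""

import numpy as np
import pytest

from hmmdfc import dynamics as dyn


def oracle_runs(path, segments):
    """Independent run-length encoder: walk each segment frame by frame."""
    runs = []
    start = 0
    for ln in segments:
        seg = list(path[start:start + ln])
        start += ln
        if not seg:
            continue
        cur, n = seg[0], 1
        for v in seg[1:]:
            if v == cur:
                n += 1
            else:
                runs.append((cur, n))
                cur, n = v, 1
        runs.append((cur, n))
    return runs


def oracle_metrics(path, segments, k):
    runs = oracle_runs(path, segments)
    mdt = np.full(k, np.nan)
    for s in range(k):
        lens = [n for st, n in runs if st == s]
        if lens:
            mdt[s] = sum(lens) / len(lens)
    counts = np.zeros((k, k), dtype=int)
    changes = pairs = 0
    start = 0
    for ln in segments:
        seg = path[start:start + ln]
        start += ln
        for a, b in zip(seg[:-1], seg[1:]):
            counts[a, b] += 1
            pairs += 1
            changes += a != b
    sw = changes / pairs if pairs else float("nan")
    return mdt, sw, counts


def random_segmented_path(rng, k):
    t = int(rng.integers(1, 60))
    path = rng.integers(0, k, size=t)
    segments = []
    rest = t
    while rest > 0:
        ln = int(rng.integers(1, rest + 1))
        segments.append(ln)
        rest -= ln
    return path, segments


def test_metrics_match_runlength_oracle_on_random_paths(rng):
    """MDT, switching rate and transition counts agree exactly with a
    frame-by-frame oracle on 1,000 random multi-segment paths."""
    for _ in range(1000):
        k = int(rng.integers(1, 6))
        path, segments = random_segmented_path(rng, k)
        mdt_o, sw_o, counts_o = oracle_metrics(path, segments, k)
        np.testing.assert_array_equal(
            dyn.mean_dwell_time(path, segments, k), mdt_o)
        counts = dyn.transition_counts(path, segments, k)
        np.testing.assert_array_equal(counts, counts_o)
        sw = dyn.switching_rate(path, segments)
        if np.isnan(sw_o):
            assert np.isnan(sw)
        else:
            assert sw == sw_o
        # pair-counting identity
        assert counts.sum() == sum(ln - 1 for ln in segments)


def test_run_length_conservation(rng):
    """Sum over states of (number of runs x MDT) equals T."""
    for _ in range(200):
        k = int(rng.integers(1, 5))
        path, segments = random_segmented_path(rng, k)
        runs = dyn.run_lengths(path, segments)
        mdt = dyn.mean_dwell_time(path, segments, k)
        total = 0.0
        for s in range(k):
            n_runs = sum(1 for st, _ in runs if st == s)
            if n_runs:
                total += n_runs * mdt[s]
        assert total == pytest.approx(len(path))


@pytest.mark.parametrize("path,segments,expected", [
    ([0, 0, 1, 1, 1, 0], [6], (1.5, 3.0)),
    ([0, 0, 1, 1, 1, 0], [3, 3], (1.5, 1.5)),   # no merge across boundary
])
def test_mdt_hand_examples(path, segments, expected):
    mdt = dyn.mean_dwell_time(np.array(path), segments, 2)
    assert tuple(mdt) == expected


def test_mdt_missing_state_is_nan():
    mdt = dyn.mean_dwell_time(np.zeros(5, dtype=int), [5], 3)
    assert mdt[0] == 5.0 and np.isnan(mdt[1]) and np.isnan(mdt[2])


@pytest.mark.parametrize("path,segments,expected", [
    ([0, 0, 0, 0], [4], 0.0),
    ([0, 1, 0, 1], [4], 1.0),
    ([0, 0, 1, 1], [2, 2], 0.0),   # change straddles boundary: not counted
])
def test_switching_rate_hand_examples(path, segments, expected):
    assert dyn.switching_rate(np.array(path), segments) == expected


def test_switching_rate_undefined_for_singleton_segments():
    assert np.isnan(dyn.switching_rate(np.array([0, 1, 0]), [1, 1, 1]))


def test_fo_soft_posteriors():
    gamma = np.tile([[1, 0], [0, 1]], (3, 1))     # alternating one-hot, T=6
    np.testing.assert_allclose(dyn.fractional_occupancy(gamma), [0.5, 0.5])
    uniform = np.full((8, 4), 0.25)
    np.testing.assert_allclose(dyn.fractional_occupancy(uniform),
                               [0.25] * 4)


def test_fo_one_hot_equals_viterbi_frequencies(rng):
    k = 4
    path = rng.integers(0, k, size=50)
    gamma = np.eye(k)[path]
    freq = np.bincount(path, minlength=k) / 50
    np.testing.assert_allclose(dyn.fractional_occupancy(gamma), freq)
    assert dyn.fractional_occupancy(gamma).sum() == pytest.approx(1.0)


def test_subject_tpm_hand_example():
    counts, tpm, empty = dyn.subject_tpm(np.array([0, 0, 1, 1, 0]), [5], 2)
    np.testing.assert_array_equal(counts, [[1, 1], [1, 1]])
    np.testing.assert_allclose(tpm, [[0.5, 0.5], [0.5, 0.5]])
    assert not empty.any()


def test_subject_tpm_empty_row_flagged():
    counts, tpm, empty = dyn.subject_tpm(np.zeros(5, dtype=int), [5], 2)
    np.testing.assert_array_equal(counts, [[4, 0], [0, 0]])
    assert not empty[0] and empty[1]
    np.testing.assert_array_equal(tpm[1], [0.0, 0.0])


def test_group_mean_tpm_skips_empty_rows():
    t1 = np.array([[1.0, 0.0], [0.0, 0.0]])
    t2 = np.array([[0.0, 1.0], [0.5, 0.5]])
    mean, n = dyn.group_mean_tpm([t1, t2],
                                 [np.array([False, True]),
                                  np.array([False, False])])
    np.testing.assert_allclose(mean[0], [0.5, 0.5])
    np.testing.assert_allclose(mean[1], [0.5, 0.5])   # only subject 2
    np.testing.assert_array_equal(n, [2, 1])


def test_group_mean_tpm_identity_and_average():
    t = np.array([[0.7, 0.3], [0.2, 0.8]])
    mean, _ = dyn.group_mean_tpm([t, t])
    np.testing.assert_allclose(mean, t)
    a = np.array([[1.0, 0.0], [1.0, 0.0]])
    b = np.array([[0.0, 1.0], [0.0, 1.0]])
    mean, _ = dyn.group_mean_tpm([a, b])
    np.testing.assert_allclose(mean, 0.5)
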