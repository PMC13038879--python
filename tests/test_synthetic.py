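"""Ground-truth generator: determinism, chain statistics, coupling."""

import numpy as np
import pytest

from hmmdfc import synthetic, dynamics as dyn


def test_spec_validates_and_k1_degenerate():
    spec = synthetic.build_spec(k_true=1, n_rois=6, n_networks=2,
                                n_per_group=2, t_per_subject=20,
                                patient_self={})
    np.testing.assert_allclose(spec.transmats["control"], [[1.0]])


def test_block_covariance_positive_definite(tiny_atlas):
    cov = synthetic.block_covariance(tiny_atlas, ["VN"], r_high=0.4,
                                     r_low=0.1, r_cross=0.05)
    assert np.linalg.eigvalsh(cov).min() > 0
    assert cov[0, 1] == 0.4 and cov[2, 3] == 0.1 and cov[0, 2] == 0.05


def test_invalid_block_correlation_rejected(tiny_atlas):
    with pytest.raises(ValueError):
        synthetic.block_covariance(tiny_atlas, ["VN"], r_high=1.0)


def test_state_signatures_distinct(small_spec):
    k = small_spec.k_true
    for i in range(k):
        for j in range(i + 1, k):
            assert not np.allclose(small_spec.covariances[i],
                                   small_spec.covariances[j])


def test_elevated_self_transition_raises_stationary_occupancy():
    spec = synthetic.test_scale_spec()
    s_star = spec.clinical_target_state
    pi_c = synthetic._stationary(spec.transmats["control"])
    pi_p = synthetic._stationary(spec.transmats["patient"])
    assert pi_p[s_star] > pi_c[s_star]


def test_simulate_subject_deterministic(small_spec):
    a, ta = synthetic.simulate_subject(small_spec, "patient", (1, 5))
    b, tb = synthetic.simulate_subject(small_spec, "patient", (1, 5))
    np.testing.assert_array_equal(a.data, b.data)
    np.testing.assert_array_equal(a.fd_trace, b.fd_trace)
    np.testing.assert_array_equal(ta.path, tb.path)
    c, _ = synthetic.simulate_subject(small_spec, "patient", (1, 6))
    assert not np.array_equal(a.data, c.data)


def test_empirical_transitions_match_generating_chain():
    """Law of large numbers: at T=10,000 the empirical transition
    frequencies sit within L1 0.05 of the generating rows."""
    spec = synthetic.build_spec(k_true=3, n_rois=6, n_networks=2,
                                n_per_group=1, t_per_subject=10_000,
                                patient_self={}, master_seed=3)
    _, truth = synthetic.simulate_subject(spec, "control", 3)
    counts = dyn.transition_counts(truth.path, [10_000], 3)
    emp = counts / counts.sum(axis=1, keepdims=True)
    l1 = np.abs(emp - spec.transmats["control"]).sum(axis=1)
    assert l1.max() < 0.05


def test_fo_converges_to_stationary_distribution():
    spec = synthetic.build_spec(k_true=3, n_rois=6, n_networks=2,
                                n_per_group=1, t_per_subject=100_000,
                                patient_self={}, master_seed=11)
    _, truth = synthetic.simulate_subject(spec, "control", 11)
    fo = np.bincount(truth.path, minlength=3) / truth.path.size
    pi = synthetic._stationary(spec.transmats["control"])
    assert np.abs(fo - pi).sum() < 0.02


def test_separated_means_allow_frame_classification():
    """With 10-SD-separated emission means, per-frame ML labeling
    recovers the true path almost everywhere."""
    spec = synthetic.build_spec(k_true=2, n_rois=4, n_networks=2,
                                n_per_group=1, t_per_subject=2000,
                                patient_self={}, mean_shift=10.0,
                                master_seed=5)
    ts, truth = synthetic.simulate_subject(spec, "control", 5)
    from scipy.stats import multivariate_normal
    ll = np.stack([multivariate_normal.logpdf(
        ts.data, spec.means[k], spec.covariances[k]) for k in range(2)])
    assert (ll.argmax(axis=0) == truth.path).mean() >= 0.99


def test_cohort_structure_and_clinical_ranges(small_cohort, small_spec):
    cohort, truth = small_cohort
    assert len(cohort.subjects) == 2 * small_spec.n_per_group
    groups = {s.group for s in cohort.subjects}
    assert groups == {"control", "patient"}
    pat = cohort.clinical.dropna(how="all")
    assert (pat["vas"].dropna().between(0, 10)).all()
    assert (pat["hit6"].dropna().between(36, 78)).all()
    assert (pat["midas"].dropna() >= 0).all()
    # controls carry no clinical scores
    ctrl_ids = [s.subject_id for s in cohort.subjects
                if s.group == "control"]
    assert cohort.clinical.loc[ctrl_ids].isna().all().all()


def test_paths_only_matches_full_simulation(small_spec):
    _, truth_full = synthetic.simulate_cohort(small_spec)
    truth_paths = synthetic.simulate_paths(small_spec)
    for a, b in zip(truth_full.subjects, truth_paths.subjects):
        assert a.subject_id == b.subject_id
        np.testing.assert_array_equal(a.path, b.path)


def test_clinical_coupling_hits_target_over_replicates():
    """Mean sample correlation between MIDAS and true target-state dwell
    time lands near the configured target across replicate cohorts."""
    rs = []
    for rep in range(40):
        spec = synthetic.test_scale_spec(master_seed=1000 + rep,
                                         n_per_group=50,
                                         clinical_target_r=0.4)
        truth = synthetic.simulate_paths(spec)
        clin = synthetic.simulate_clinical(spec, truth)
        pats = [s for s in truth.subjects if s.group == "patient"]
        mdt = np.array([dyn.mean_dwell_time(
            s.path, [len(s.path)], spec.k_true)[
                spec.clinical_target_state] for s in pats])
        midas = clin.loc[[s.subject_id for s in pats], "midas"].to_numpy()
        rs.append(np.corrcoef(mdt, midas)[0, 1])
    assert 0.35 <= np.mean(rs) <= 0.45


def test_zero_coupling_gives_null_correlation():
    spec = synthetic.test_scale_spec(master_seed=77, n_per_group=100,
                                     clinical_target_r=0.0)
    truth = synthetic.simulate_paths(spec)
    clin = synthetic.simulate_clinical(spec, truth)
    pats = [s for s in truth.subjects if s.group == "patient"]
    mdt = np.array([dyn.mean_dwell_time(
        s.path, [len(s.path)], spec.k_true)[
            spec.clinical_target_state] for s in pats])
    midas = clin.loc[[s.subject_id for s in pats], "midas"].to_numpy()
    r = np.corrcoef(mdt, midas)[0, 1]
    assert abs(r) < 2.2 / np.sqrt(len(pats))    # inside the null 95% band


def test_too_many_states_for_networks_rejected():
    with pytest.raises(ValueError, match="signatures"):
        synthetic.build_spec(k_true=4, n_rois=10, n_networks=2,
                             n_per_group=1, t_per_subject=10)
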