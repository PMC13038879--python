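"""HMM engine: BIC arithmetic, fitting contracts, alignment, decoding."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from hmmdfc import hmm, prep, synthetic
from hmmdfc.prep import ConcatenatedSeries
from hmmdfc.types import ValidationError

from conftest import prep_cohort


def make_x(data, lengths=None, owners=None):
    lengths = lengths or [data.shape[0]]
    owners = owners or [f"s{i}" for i in range(len(lengths))]
    return ConcatenatedSeries(data=np.asarray(data, float),
                              lengths=lengths, segment_owner=owners)


@pytest.mark.parametrize("k,n,expected", [
    (2, 2, 13),
    (1, 1, 2),
    (11, 142, 113_365),
])
def test_count_params_formula(k, n, expected):
    assert hmm.count_params(k, n) == expected


def test_bic_closed_form_and_monotonicity():
    assert hmm.bic(-100.0, 13, 50) == pytest.approx(200 + 13 * np.log(50))
    assert hmm.bic(-100.0, 10, 50) < hmm.bic(-100.0, 13, 50)
    assert hmm.bic(-100.0, 13, 100) - hmm.bic(-100.0, 13, 50) == \
        pytest.approx(13 * np.log(2))
    with pytest.raises(ValueError):
        hmm.bic(-100.0, 13, 1)


def test_fit_k1_recovers_sample_moments(rng):
    """K=1 EM has a closed form: the Gaussian MLE of the pooled sample."""
    data = rng.multivariate_normal([1.0, -2.0, 0.5],
                                   [[2.0, 0.3, 0.0], [0.3, 1.0, 0.2],
                                    [0.0, 0.2, 0.5]], size=600)
    x = make_x(data, [300, 300], ["a", "b"])
    m = hmm.fit_hmm(x, 1, seed=0)
    np.testing.assert_allclose(m.means[0], data.mean(axis=0), atol=1e-6)
    np.testing.assert_allclose(m.covariances[0],
                               np.cov(data.T, ddof=0), atol=1e-4)
    direct = multivariate_normal.logpdf(data, m.means[0],
                                        m.covariances[0]).sum()
    assert m.log_likelihood == pytest.approx(direct, abs=1e-4)


def test_fit_deterministic_given_seed(small_cohort):
    cohort = prep_cohort(small_cohort[0])
    x = prep.concatenate(cohort)
    a = hmm.fit_hmm(x, 3, seed=5, max_iter=15, tol=1e-4)
    b = hmm.fit_hmm(x, 3, seed=5, max_iter=15, tol=1e-4)
    assert a.log_likelihood == b.log_likelihood
    np.testing.assert_array_equal(a.transmat, b.transmat)


def test_em_loglik_monotone(small_cohort):
    cohort = prep_cohort(small_cohort[0])
    x = prep.concatenate(cohort)
    m = hmm.fit_hmm(x, 3, seed=1, max_iter=40, tol=1e-4)
    diffs = np.diff(m.loglik_history)
    assert diffs.min() >= -1e-8 * abs(m.log_likelihood)


def test_fit_rejects_bad_inputs(rng):
    x = make_x(rng.normal(size=(20, 5)))
    with pytest.raises(ValueError):
        hmm.fit_hmm(x, 0, seed=0)
    with pytest.raises(ValidationError, match="too few frames"):
        hmm.fit_hmm(x, 5, seed=0)


def test_align_states_inverts_a_known_permutation(small_spec):
    covs = small_spec.covariances
    perm = np.array([2, 0, 3, 1])
    mapping, sim = hmm.align_states(covs, covs[perm])
    # reordering the permuted stack by `mapping` restores the original
    np.testing.assert_array_equal(covs[perm][mapping], covs)
    np.testing.assert_allclose(sim, 1.0, atol=1e-12)


def test_align_states_degenerate_ties_identity():
    cov = np.eye(3) + 0.2
    stack = np.stack([cov, cov, cov])
    mapping, _ = hmm.align_states(stack, stack)
    np.testing.assert_array_equal(mapping, [0, 1, 2])


def test_align_states_shape_mismatch():
    with pytest.raises(ValidationError):
        hmm.align_states(np.stack([np.eye(3)] * 2),
                         np.stack([np.eye(4)] * 2))


def test_permute_model_states_roundtrip(small_spec):
    m = hmm.GaussianHMMModel(
        k=4, means=small_spec.means, covariances=small_spec.covariances,
        transmat=small_spec.transmats["control"],
        startprob=small_spec.startprobs["control"], log_likelihood=0.0,
        n_params=0, bic=0.0, seed=0, n_iter_used=0, converged=True)
    perm = np.array([3, 1, 0, 2])
    back = hmm.permute_model_states(hmm.permute_model_states(m, perm),
                                    np.argsort(perm))
    np.testing.assert_array_equal(back.transmat, m.transmat)


def test_decode_k1_trivial(rng):
    data = rng.normal(size=(50, 3))
    x = make_x(data, [25, 25], ["a", "a"])
    m = hmm.fit_hmm(x, 1, seed=0)
    seqs = hmm.decode(m, x)
    assert set(seqs) == {"a"}
    np.testing.assert_array_equal(seqs["a"].viterbi, 0)
    np.testing.assert_allclose(seqs["a"].gamma, 1.0)


def test_decode_separable_states_and_gamma_rows(rng):
    """Two states with means +-10 SD apart: decoding matches the
    generating path on >= 99% of frames; gamma rows are distributions."""
    spec = synthetic.build_spec(k_true=2, n_rois=4, n_networks=2,
                                n_per_group=1, t_per_subject=1500,
                                patient_self={}, mean_shift=10.0,
                                master_seed=9)
    ts, truth = synthetic.simulate_subject(spec, "control", 9, "a")
    x = make_x(ts.data, [1500], ["a"])
    model = hmm.GaussianHMMModel(
        k=2, means=spec.means, covariances=spec.covariances,
        transmat=spec.transmats["control"],
        startprob=spec.startprobs["control"], log_likelihood=0.0,
        n_params=0, bic=0.0, seed=0, n_iter_used=0, converged=True)
    seq = hmm.decode(model, x)["a"]
    agree = (seq.viterbi == truth.path).mean()
    assert max(agree, 1 - agree) >= 0.99     # label order is arbitrary
    np.testing.assert_allclose(seq.gamma.sum(axis=1), 1.0, atol=1e-8)


def test_decoded_transitions_respect_segment_boundaries(small_cohort):
    """Viterbi restarts at each segment: reconstruction from per-segment
    decodes matches the joint decode exactly."""
    cohort = prep_cohort(small_cohort[0])
    x = prep.concatenate(cohort)
    m = hmm.fit_hmm(x, 3, seed=2, max_iter=20, tol=1e-2)
    seqs = hmm.decode(m, x)
    # decode each segment of one multi-segment subject separately
    multi = next(s for s in cohort.subjects if len(s.segments) > 1)
    start = 0
    pieces = []
    for ln in multi.segments:
        xi = make_x(multi.data[start:start + ln], [ln], ["seg"])
        pieces.append(hmm.decode(m, xi)["seg"].viterbi)
        start += ln
    np.testing.assert_array_equal(np.concatenate(pieces),
                                  seqs[multi.subject_id].viterbi)


def test_select_k_single_value_grid(small_cohort):
    cohort = prep_cohort(small_cohort[0])
    x = prep.concatenate(cohort)
    sel = hmm.select_k(x, k_min=3, k_max=3, n_seeds=2, master_seed=0,
                       max_iter=15, tol=1e-2)
    assert sel.chosen_k == 3
    assert len(sel.table) == 1


def test_select_k_seed_permutation_invariant(small_cohort):
    """The best-of-restarts log-likelihood is a max over the same seed
    set regardless of order."""
    cohort = prep_cohort(small_cohort[0])
    x = prep.concatenate(cohort)
    fits = [hmm.fit_hmm(x, 2, seed=s, max_iter=15, tol=1e-2)
            for s in (0, 1, 2)]
    best = max(f.log_likelihood for f in fits)
    sel = hmm.select_k(x, k_min=2, k_max=2, n_seeds=3, master_seed=0,
                       max_iter=15, tol=1e-2)
    assert sel.table["log_likelihood"].iloc[0] == best


def test_model_json_roundtrip(tmp_path, small_cohort):
    cohort = prep_cohort(small_cohort[0])
    x = prep.concatenate(cohort)
    m = hmm.fit_hmm(x, 2, seed=0, max_iter=10, tol=1e-2)
    m.to_json(tmp_path / "m.json")
    back = hmm.GaussianHMMModel.from_json(tmp_path / "m.json")
    np.testing.assert_array_equal(back.covariances, m.covariances)
    assert back.bic == m.bic


def test_robustness_refit_pca_recovers_state_patterns():
    """At N = 40 the dimensionality-reduced refit (top-30 components,
    K +- 2 range) reproduces the full-space states: mean back-projected
    pattern correlation above 0.8 and a monotone explained-variance
    spectrum."""
    spec = synthetic.test_scale_spec(master_seed=21, n_rois=40,
                                     n_per_group=10, t_per_subject=150,
                                     patient_self={}, fd_spike_prob=0.0)
    cohort, _ = synthetic.simulate_cohort(spec)
    x = prep.concatenate(prep_cohort(cohort))
    full = hmm.fit_hmm(x, 4, seed=0, max_iter=50, tol=5e-2)
    rep = hmm.robustness_refit(x, 4, full, master_seed=0, n_seeds=1,
                               max_iter=40, tol=5e-2)
    assert rep.pca_used and rep.n_components == 30
    evr = np.asarray(rep.explained_variance_ratio)
    assert evr.shape == (30,) and np.all(np.diff(evr) <= 1e-12)
    assert rep.mean_matched_similarity > 0.8
    assert len(rep.bic_profile) == 5


def test_robustness_refit_skips_pca_when_small(small_cohort):
    cohort = prep_cohort(small_cohort[0])
    x = prep.concatenate(cohort)
    m = hmm.fit_hmm(x, 3, seed=0, max_iter=15, tol=1e-2)
    rep = hmm.robustness_refit(x, 3, m, n_seeds=1, max_iter=15, tol=1e-2)
    assert not rep.pca_used
    assert rep.mean_matched_similarity is not None
    assert {"K", "bic"}.issubset(rep.bic_profile.columns)
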