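"""Gaussian HMM fitting, model selection, alignment, decoding.

The observation model is a K-state Gaussian HMM with full covariance per
state, fitted by EM on the concatenated multi-subject matrix.  The segment
lengths ledger is passed to every forward-backward and Viterbi recursion,
so probability never flows across a scrubbing gap or between participants.

Model selection is a grid search over K with multi-seed restarts: for each
K the restart with the highest log-likelihood is kept, and the number of
states is chosen at the global minimum of BIC = -2 logL + n_params ln(T),
with T the total number of concatenated frames and the free-parameter
count (K-1) + K(K-1) + KN + KN(N+1)/2 (initial distribution, transition
matrix, means, covariances).  Ties in BIC break toward smaller K.

Because state labels are arbitrary, models are compared after alignment:
each state's covariance is converted to a correlation matrix, its strict
lower triangle vectorized, a K x K Pearson-correlation similarity built
between the two models' states, and the Hungarian assignment maximizing
total similarity taken as the label permutation.

EM internals (E-step, M-step, Viterbi) are delegated to hmmlearn's
``GaussianHMM``; this module owns the selection, alignment, BIC,
diagnostics and segment bookkeeping contracts around it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM as _HLGaussianHMM
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .prep import ConcatenatedSeries
from .types import ValidationError

logger = logging.getLogger(__name__)

COV_FLOOR = 1e-6


@dataclass
class GaussianHMMModel:
    """A fitted model: parameters plus fit diagnostics."""

    k: int
    means: np.ndarray          # K x N
    covariances: np.ndarray    # K x N x N
    transmat: np.ndarray       # K x K row-stochastic
    startprob: np.ndarray      # length K
    log_likelihood: float
    n_params: int
    bic: float
    seed: int
    n_iter_used: int
    converged: bool
    loglik_history: list[float] = field(default_factory=list, repr=False)

    @property
    def n_rois(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("transmat rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-8):
            raise ValidationError("startprob must sum to 1")
        for s in range(self.k):
            if np.linalg.eigvalsh(self.covariances[s]).min() <= 0:
                raise ValidationError(
                    f"state {s}: covariance not positive definite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "bic": self.bic,
            "seed": self.seed,
            "n_iter_used": self.n_iter_used,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianHMMModel":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], means=np.array(d["means"]),
                   covariances=np.array(d["covariances"]),
                   transmat=np.array(d["transmat"]),
                   startprob=np.array(d["startprob"]),
                   log_likelihood=d["log_likelihood"],
                   n_params=d["n_params"], bic=d["bic"], seed=d["seed"],
                   n_iter_used=d["n_iter_used"], converged=d["converged"])


@dataclass
class StateSequence:
    """One subject's decoded path and posteriors."""

    subject_id: str
    viterbi: np.ndarray        # length T, values 0..K-1
    gamma: np.ndarray          # T x K, rows sum to 1


@dataclass
class ModelSelectionResult:
    table: pd.DataFrame        # K, log_likelihood, bic, seed, converged
    chosen_k: int
    models: dict[int, GaussianHMMModel] = field(default_factory=dict)


def count_params(k: int, n: int) -> int:
    """Free parameters of a K-state full-covariance Gaussian HMM on N
    dimensions: (K-1) + K(K-1) + KN + KN(N+1)/2."""
    if k < 1 or n < 1:
        raise ValueError("need k >= 1 and n >= 1")
    return (k - 1) + k * (k - 1) + k * n + k * n * (n + 1) // 2


def bic(log_likelihood: float, n_params: int, t_total: int) -> float:
    """BIC = -2 logL + n_params ln(T_total)."""
    if t_total <= 1:
        raise ValueError("t_total must exceed 1")
    return -2.0 * log_likelihood + n_params * float(np.log(t_total))


def _floor_covariances(covs: np.ndarray) -> np.ndarray:
    """Diagonal jitter so every state covariance stays positive definite."""
    covs = covs.copy()
    n = covs.shape[1]
    for s in range(covs.shape[0]):
        while np.linalg.eigvalsh(covs[s]).min() < 1e-8:
            covs[s] += COV_FLOOR * np.eye(n)
    return covs


#: Window length (frames) for the covariance-feature initialization.
INIT_WINDOW = 12


def _window_fc_features(x: ConcatenatedSeries, window: int
                        ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Vectorized correlation of non-overlapping within-segment windows.

    Returns the feature matrix and, per window, the frame indices it
    covers.  Windows never straddle a segment boundary.
    """
    n = x.data.shape[1]
    tri = np.tril_indices(n, k=-1)
    feats, members = [], []
    start = 0
    for ln in x.lengths:
        for s0 in range(start, start + ln - window + 1, window):
            seg = x.data[s0:s0 + window]
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.corrcoef(seg, rowvar=False)
            feats.append(np.nan_to_num(c[tri]))
            members.append(np.arange(s0, s0 + window))
        start += ln
    if not feats:
        return np.empty((0, tri[0].size)), []
    return np.stack(feats), members


def _informed_init(x: ConcatenatedSeries, k: int, seed: int,
                   window: int = INIT_WINDOW):
    """Covariance-aware EM initialization.

    Frame-level k-means (hmmlearn's default) is blind to states that
    differ only in second moments — on zero-mean connectivity-defined
    states it is no better than random.  Instead, short within-segment
    windows are summarized by their vectorized correlation pattern,
    k-means clusters those patterns (restart seeds vary the clustering),
    and each state starts from the pooled moments of its cluster's
    frames.  Returns None when the data yield fewer windows than states.
    """
    from sklearn.cluster import KMeans

    feats, members = _window_fc_features(x, window)
    if len(members) < k:
        return None
    km = KMeans(n_clusters=k, random_state=int(seed) & 0x7FFFFFFF,
                n_init=3).fit(feats)
    n = x.data.shape[1]
    means = np.zeros((k, n))
    covs = np.zeros((k, n, n))
    for s in range(k):
        hit = np.flatnonzero(km.labels_ == s)
        idx = np.concatenate([members[i] for i in hit]) if hit.size \
            else np.arange(x.data.shape[0])
        sub = x.data[idx]
        means[s] = sub.mean(axis=0)
        covs[s] = np.cov(sub.T, ddof=0).reshape(n, n) \
            + 1e-4 * np.eye(n)
    transmat = np.full((k, k), 0.2 / max(k - 1, 1))
    np.fill_diagonal(transmat, 0.8)
    if k == 1:
        transmat = np.ones((1, 1))
    return np.full(k, 1.0 / k), transmat, means, covs


def fit_hmm(x: ConcatenatedSeries, k: int, seed: int,
            max_iter: int = 500, tol: float = 1e-4) -> GaussianHMMModel:
    """Fit one K-state model by EM from one seeded initialization.

    Initialization clusters windowed connectivity patterns (see
    :func:`_informed_init`); when the data are too short for that,
    hmmlearn's default frame-level k-means init is used.  Raises if EM
    ever decreases the log-likelihood (beyond numerical noise) or
    produces a non-finite likelihood.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t_total, n = x.data.shape
    if t_total < k * (n + 1):
        raise ValidationError(
            f"too few frames ({t_total}) to fit K={k} states on N={n} ROIs")
    init = _informed_init(x, k, seed)
    hl = _HLGaussianHMM(n_components=k, covariance_type="full",
                        n_iter=max_iter, tol=tol,
                        random_state=int(seed) & 0x7FFFFFFF,
                        min_covar=COV_FLOOR, covars_prior=COV_FLOOR,
                        init_params="stmc" if init is None else "",
                        params="stmc")
    if init is not None:
        hl.startprob_, hl.transmat_, hl.means_, covs0 = init
        hl.covars_ = _floor_covariances(covs0)
    hl.fit(x.data, lengths=x.lengths)
    history = list(hl.monitor_.history)
    if not history or not np.isfinite(history[-1]):
        bad = next((i for i, v in enumerate(history)
                    if not np.isfinite(v)), len(history))
        raise ValidationError(
            f"non-finite log-likelihood at EM iteration {bad}")
    diffs = np.diff(history)
    slack = 1e-8 * max(1.0, abs(history[-1]))
    if diffs.size and diffs.min() < -slack:
        i = int(np.argmin(diffs))
        raise ValidationError(
            f"EM log-likelihood decreased at iteration {i + 1} "
            f"(delta {diffs[i]:.3e})")
    covs = _floor_covariances(hl.covars_)
    npar = count_params(k, n)
    logl = float(history[-1])
    # converged means the EM gain actually fell below tol, not that the
    # iteration budget ran out
    tol_reached = len(history) >= 2 and \
        (history[-1] - history[-2]) < tol
    model = GaussianHMMModel(
        k=k, means=hl.means_.copy(), covariances=covs,
        transmat=hl.transmat_.copy(), startprob=hl.startprob_.copy(),
        log_likelihood=logl, n_params=npar,
        bic=bic(logl, npar, t_total), seed=int(seed),
        n_iter_used=len(history), converged=tol_reached,
        loglik_history=history)
    model.validate()
    return model


def select_k(x: ConcatenatedSeries, k_min: int = 2, k_max: int = 14,
             n_seeds: int = 10, master_seed: int = 0, max_iter: int = 500,
             tol: float = 1e-4,
             keep_models: bool = True) -> ModelSelectionResult:
    """Grid search over K with multi-seed restarts and BIC selection.

    For each K, ``n_seeds`` restarts (seeds master_seed + 0..n_seeds-1)
    are fitted and the max-log-likelihood restart kept; the chosen K
    minimizes BIC over the grid, ties breaking toward smaller K.  A K
    whose every restart fails is recorded and excluded from the argmin.
    """
    if k_max < k_min:
        raise ValueError("empty K grid")
    rows = []
    models: dict[int, GaussianHMMModel] = {}
    for k in range(k_min, k_max + 1):
        best: GaussianHMMModel | None = None
        for s in range(n_seeds):
            seed = master_seed + s
            try:
                m = fit_hmm(x, k, seed, max_iter=max_iter, tol=tol)
            except (ValidationError, np.linalg.LinAlgError) as exc:
                logger.warning("K=%d seed=%d failed: %s", k, seed, exc)
                continue
            if best is None or m.log_likelihood > best.log_likelihood:
                best = m
        if best is None:
            logger.warning("K=%d: all restarts failed; excluded", k)
            rows.append({"K": k, "log_likelihood": np.nan, "bic": np.nan,
                         "seed": -1, "converged": False, "failed": True})
            continue
        rows.append({"K": k, "log_likelihood": best.log_likelihood,
                     "bic": best.bic, "seed": best.seed,
                     "converged": best.converged, "failed": False})
        if keep_models:
            models[k] = best
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise ValidationError("model selection failed for every K")
    # idxmin on the K-sorted table breaks BIC ties toward smaller K
    chosen = int(ok.loc[ok["bic"].idxmin(), "K"])
    return ModelSelectionResult(table=table, chosen_k=chosen, models=models)


def _correlation_from_cov(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _fc_vectors(covariances: np.ndarray) -> np.ndarray:
    """Per state, the strict lower triangle of the correlation matrix."""
    k, n, _ = covariances.shape
    tri = np.tril_indices(n, k=-1)
    return np.stack([_correlation_from_cov(covariances[s])[tri]
                     for s in range(k)])


def align_states(reference: GaussianHMMModel | np.ndarray,
                 other: GaussianHMMModel | np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Match the other model's states to the reference's.

    Both arguments may be models or raw K x N x N covariance stacks.
    Returns ``(mapping, similarity)``: ``mapping[i]`` is the other-model
    state assigned to reference state ``i`` (so reordering the other
    model's states by ``mapping`` aligns it with the reference), and
    ``similarity[i]`` the Pearson correlation of the matched pair's
    vectorized FC patterns.  When all pairings tie, the Hungarian solver's
    deterministic lowest-index assignment (the identity) is returned.
    """
    ref_cov = reference.covariances if hasattr(reference, "covariances") \
        else np.asarray(reference)
    oth_cov = other.covariances if hasattr(other, "covariances") \
        else np.asarray(other)
    if ref_cov.shape != oth_cov.shape:
        raise ValidationError("models must share K and N for alignment")
    vr, vo = _fc_vectors(ref_cov), _fc_vectors(oth_cov)
    k = vr.shape[0]
    sim = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = np.corrcoef(vr[i], vo[j])[0, 1]
    sim = np.nan_to_num(sim)
    rows, cols = linear_sum_assignment(-sim)
    mapping = cols[np.argsort(rows)]
    return mapping, sim[np.arange(k), mapping]


def permute_model_states(model: GaussianHMMModel,
                         mapping: np.ndarray) -> GaussianHMMModel:
    """Relabel states so that new state i = old state ``mapping[i]``."""
    m = np.asarray(mapping)
    return GaussianHMMModel(
        k=model.k, means=model.means[m],
        covariances=model.covariances[m],
        transmat=model.transmat[np.ix_(m, m)],
        startprob=model.startprob[m],
        log_likelihood=model.log_likelihood, n_params=model.n_params,
        bic=model.bic, seed=model.seed, n_iter_used=model.n_iter_used,
        converged=model.converged,
        loglik_history=list(model.loglik_history))


def _to_hmmlearn(model: GaussianHMMModel) -> _HLGaussianHMM:
    hl = _HLGaussianHMM(n_components=model.k, covariance_type="full",
                        init_params="", params="stmc")
    hl.startprob_ = model.startprob
    hl.transmat_ = model.transmat
    hl.means_ = model.means
    hl.covars_ = model.covariances
    return hl


def decode(model: GaussianHMMModel,
           x: ConcatenatedSeries) -> dict[str, StateSequence]:
    """Viterbi path and posteriors gamma per subject.

    Each segment is decoded independently (the recursion restarts at every
    segment boundary), then a subject's segments are reassembled in
    temporal order.
    """
    if model.n_rois != x.n_rois:
        raise ValidationError("model and data disagree on N")
    hl = _to_hmmlearn(model)
    _, paths = hl.decode(x.data, lengths=x.lengths, algorithm="viterbi")
    gammas = hl.predict_proba(x.data, lengths=x.lengths)
    out: dict[str, StateSequence] = {}
    start = 0
    pieces: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for ln, owner in zip(x.lengths, x.segment_owner):
        pieces.setdefault(owner, []).append(
            (paths[start:start + ln], gammas[start:start + ln]))
        start += ln
    for sid, segs in pieces.items():
        out[sid] = StateSequence(
            subject_id=sid,
            viterbi=np.concatenate([p for p, _ in segs]),
            gamma=np.vstack([g for _, g in segs]))
    return out


@dataclass
class RobustnessReport:
    pca_used: bool
    n_components: int
    explained_variance_ratio: np.ndarray | None
    bic_profile: pd.DataFrame       # K, log_likelihood, bic
    matched_similarity: np.ndarray | None   # per-state, at K = chosen_k
    mean_matched_similarity: float | None


def robustness_refit(x: ConcatenatedSeries, chosen_k: int,
                     reference: GaussianHMMModel, master_seed: int = 0,
                     n_components: int = 30, n_seeds: int = 3,
                     max_iter: int = 200,
                     tol: float = 1e-4) -> RobustnessReport:
    """Dimensionality-reduction robustness check.

    Projects the concatenated data onto its top principal components
    (default 30), refits models over chosen_k +- 2, and reports the BIC
    profile plus, at K = chosen_k, the per-state FC-pattern correlation
    between the reference full-space states and the refit states'
    back-projected covariances.  When N <= n_components the projection
    would be (at most) a rotation, so PCA is skipped and models are refit
    in the original space.
    """
    t_total, n = x.data.shape
    pca_used = n > n_components
    if pca_used:
        pca = PCA(n_components=n_components, svd_solver="full")
        proj = pca.fit_transform(x.data)
        evr = pca.explained_variance_ratio_
        if np.any(np.diff(evr) > 1e-12):
            raise AssertionError("PCA explained variance not sorted")
    else:
        logger.warning("PCA skipped: N=%d <= %d components", n,
                       n_components)
        pca, proj, evr = None, x.data, None
    xp = ConcatenatedSeries(data=proj, lengths=list(x.lengths),
                            segment_owner=list(x.segment_owner),
                            subject_segments=dict(x.subject_segments),
                            subject_group=dict(x.subject_group))
    rows = []
    matched = None
    for k in range(max(1, chosen_k - 2), chosen_k + 3):
        best = None
        for s in range(n_seeds):
            try:
                m = fit_hmm(xp, k, master_seed + s, max_iter=max_iter,
                            tol=tol)
            except (ValidationError, np.linalg.LinAlgError):
                continue
            if best is None or m.log_likelihood > best.log_likelihood:
                best = m
        if best is None:
            rows.append({"K": k, "log_likelihood": np.nan, "bic": np.nan})
            continue
        rows.append({"K": k, "log_likelihood": best.log_likelihood,
                     "bic": best.bic})
        if k == chosen_k:
            if pca_used:
                back = np.stack([
                    pca.components_.T @ best.covariances[s]
                    @ pca.components_ for s in range(k)])
                # keep the back-projected covariance invertible for the
                # correlation conversion
                back += COV_FLOOR * np.eye(n)
            else:
                back = best.covariances
            _, matched = align_states(reference, back)
    return RobustnessReport(
        pca_used=pca_used,
        n_components=n_components if pca_used else n,
        explained_variance_ratio=evr,
        bic_profile=pd.DataFrame(rows),
        matched_similarity=matched,
        mean_matched_similarity=float(np.mean(matched))
        if matched is not None else None)
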