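"""Ground-truth generator for two-group brain-state cohorts.

Each subject's BOLD matrix is simulated from a Gaussian hidden Markov
model: a state path is drawn from the subject's group-specific Markov
chain, then each frame is drawn from that state's multivariate normal
emission.  State identity is carried by network-structured covariance
(means default to zero): every state elevates a distinct *subset* of
networks to within-network correlation ``r_high`` (the subset is state
index s+1 read as a bit pattern over the networks, so no two states
share a signature and every state elevates at least one network) while
the remaining networks sit at ``r_low``, with
``r_cross`` between networks — the connectivity-centric regime in which
brain states differ by coupling pattern, not amplitude.

Group structure is injected through the transition matrices: designated
states get elevated self-transition probability in the patient group
(raising their stationary occupancy and dwell time) and others get reduced
self-transition, mimicking the dual pattern of state "locking" plus
depleted baseline states reported in migraine.  A disability-like clinical
score (MIDAS) is coupled to the true dwell time of one target state with a
configurable population correlation; other scales (VAS, HIT-6, SDS,
disease duration, monthly headache days) are drawn from realistic
uncoupled distributions.

Defaults emulate the study conditions this pipeline is designed for:
230 retained volumes at TR = 2 s, 142 ROIs over 7 networks, 100 subjects
per group, 11 states, and a MIDAS coupling target of r = 0.38.  Use
:func:`test_scale_spec` for a small configuration that exercises the full
pipeline in seconds.

Reproducibility: one master seed; subject ``i`` of the cohort uses
``SeedSequence((master_seed, i))`` and clinical noise uses
``SeedSequence((master_seed, 2**20))``, so subjects are independent
streams and any subject can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import mean_dwell_time
from .types import (AtlasMapping, CohortDataset, SubjectTimeSeries,
                    CANONICAL_NETWORKS)

_CLINICAL_MARGINALS = {
    # mean, sd, lower, upper  (matched to the target patient population)
    "vas": (5.6, 1.8, 0.0, 10.0),
    "hit6": (52.3, 9.0, 36.0, 78.0),
    "sds": (49.8, 6.3, 20.0, 80.0),
    "duration_years": (6.6, 4.9, 1.0, None),
}
_MIDAS_MEAN, _MIDAS_SD = 18.8, 9.2


@dataclass
class GenerativeSpec:
    """Fully materialized ground truth for one synthetic cohort."""

    k_true: int
    atlas: AtlasMapping
    means: np.ndarray                      # K x N
    covariances: np.ndarray                # K x N x N, symmetric PD
    transmats: dict[str, np.ndarray]       # group -> K x K row-stochastic
    startprobs: dict[str, np.ndarray]      # group -> length-K simplex
    n_per_group: int = 100
    t_per_subject: int = 230
    tr_seconds: float = 2.0
    # FD model: |N(fd_mean, fd_sd^2)| with spike_prob chance of a spike
    # uniform in spike_range, to exercise the scrubbing path.
    fd_mean: float = 0.05
    fd_sd: float = 0.03
    fd_spike_prob: float = 0.02
    fd_spike_range: tuple[float, float] = (0.5, 1.0)
    # clinical coupling: MIDAS_i = max(0, round(alpha + beta*MDT_i(s*) + eps))
    clinical_target_state: int = 0
    clinical_target_r: float = 0.38
    master_seed: int = 0

    @property
    def n_rois(self) -> int:
        return self.atlas.n_rois

    def validate(self) -> None:
        k, n = self.k_true, self.n_rois
        if self.means.shape != (k, n):
            raise ValueError("means must be K x N")
        if self.covariances.shape != (k, n, n):
            raise ValueError("covariances must be K x N x N")
        for s in range(k):
            cov = self.covariances[s]
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {s}: covariance not symmetric")
            mineig = float(np.linalg.eigvalsh(cov).min())
            if mineig <= 0:
                raise ValueError(
                    f"state {s}: covariance template not positive definite "
                    f"(min eigenvalue {mineig:.3e}); add diagonal jitter")
        for g, tm in self.transmats.items():
            if tm.shape != (k, k) or np.any(tm < 0) \
                    or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"group {g}: transition matrix rows must "
                                 "be stochastic")
        for g, sp in self.startprobs.items():
            if sp.shape != (k,) or np.any(sp < 0) \
                    or not np.isclose(sp.sum(), 1.0, atol=1e-8):
                raise ValueError(f"group {g}: startprob must be a simplex")
        if not 0 <= self.clinical_target_state < k:
            raise ValueError("clinical_target_state out of range")
        if not -1 < self.clinical_target_r < 1:
            raise ValueError("clinical_target_r must be in (-1, 1)")


@dataclass
class SubjectTruth:
    """What the generator knows about one subject."""

    subject_id: str
    group: str
    path: np.ndarray               # length-T true state labels


@dataclass
class GroundTruth:
    """Generator-side truth for a whole cohort."""

    spec: GenerativeSpec
    subjects: list[SubjectTruth] = field(default_factory=list)

    def true_mdt(self, subject_id: str, state: int) -> float:
        tr = next(s for s in self.subjects if s.subject_id == subject_id)
        return mean_dwell_time(tr.path, [len(tr.path)],
                               self.spec.k_true)[state]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for t, st in enumerate(s.path):
                rows.append((s.subject_id, t, int(st)))
        return pd.DataFrame(rows, columns=["subject_id", "t", "true_state"])


def block_covariance(atlas: AtlasMapping, high_networks: list[str],
                     r_high: float = 0.4, r_low: float = 0.1,
                     r_cross: float = 0.05) -> np.ndarray:
    """Unit-variance covariance with network-block correlation structure.

    Within each network in ``high_networks`` the correlation is ``r_high``;
    within every other network ``r_low``; between networks ``r_cross``.
    """
    for r in (r_high, r_low, r_cross):
        if not 0 <= r < 1:
            raise ValueError("block correlations must satisfy 0 <= r < 1")
    n = atlas.n_rois
    cov = np.full((n, n), r_cross)
    for net in atlas.network_names:
        idx = atlas.rois_in_network(net)
        r = r_high if net in high_networks else r_low
        cov[np.ix_(idx, idx)] = r
    np.fill_diagonal(cov, 1.0)
    return cov


def _stationary(tm: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(tm.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _self_transition_matrix(k: int, self_probs: np.ndarray) -> np.ndarray:
    """Row-stochastic matrix with given diagonal, off-diagonal uniform."""
    if np.any(self_probs < 0) or np.any(self_probs >= 1) and k > 1:
        raise ValueError("self-transition probabilities must be in [0, 1)")
    tm = np.zeros((k, k))
    for i in range(k):
        tm[i] = (1.0 - self_probs[i]) / max(k - 1, 1)
        tm[i, i] = self_probs[i]
    if k == 1:
        tm[:] = 1.0
    return tm


def default_atlas(n_rois: int = 142, n_networks: int = 7) -> AtlasMapping:
    """Evenly partition ``n_rois`` ROIs into the first ``n_networks``
    canonical networks."""
    nets = CANONICAL_NETWORKS[:n_networks]
    networks = [nets[i % n_networks] for i in range(n_rois)]
    # group contiguously so block structure is visible in heatmaps
    networks.sort(key=lambda x: nets.index(x))
    names = [f"ROI{i + 1:03d}" for i in range(n_rois)]
    return AtlasMapping(roi_names=names, networks=networks)


def build_spec(k_true: int = 11, n_rois: int = 142, n_networks: int = 7,
               n_per_group: int = 100, t_per_subject: int = 230,
               baseline_self: float = 0.80,
               patient_self: dict[int, float] | None = None,
               r_high: float = 0.8, r_low: float = 0.05,
               r_cross: float = 0.02, mean_shift: float = 0.0,
               clinical_target_state: int | None = None,
               clinical_target_r: float = 0.38,
               master_seed: int = 0,
               **field_overrides) -> GenerativeSpec:
    """Materialize a generative spec with group-structured dynamics.

    The control chain gives every state self-transition probability
    ``baseline_self``.  ``patient_self`` overrides the diagonal for chosen
    states in the patient group; by default the last two states are
    elevated (0.90, 0.88 — the "locked" states) and the first two reduced
    (0.72, 0.74 — depleted baseline states).  The clinical target state
    defaults to the most elevated state.

    ``mean_shift`` optionally separates state emission means (state k's
    "high" network ROIs get mean ``mean_shift``); the default 0 leaves
    state identity purely in the covariance structure.
    """
    atlas = default_atlas(n_rois, n_networks)
    nets = atlas.network_names
    if k_true > 2 ** n_networks - 1:
        raise ValueError(
            f"cannot give {k_true} states distinct non-empty network "
            f"signatures with {n_networks} networks "
            f"(max {2 ** n_networks - 1})")
    if patient_self is None:
        patient_self = {}
        if k_true >= 2:
            patient_self[k_true - 1] = 0.90
            patient_self[0] = 0.72
        if k_true >= 4:
            patient_self[k_true - 2] = 0.88
            patient_self[1] = 0.74
    if any(not 0 <= s < k_true for s in patient_self):
        raise ValueError("patient_self refers to a state out of range")

    means = np.zeros((k_true, n_rois))
    covs = np.empty((k_true, n_rois, n_rois))
    for s in range(k_true):
        high = [nets[b] for b in range(len(nets)) if ((s + 1) >> b) & 1]
        covs[s] = block_covariance(atlas, high, r_high, r_low, r_cross)
        if mean_shift:
            for net in high:
                means[s, atlas.rois_in_network(net)] = mean_shift

    ctrl_diag = np.full(k_true, baseline_self)
    pat_diag = ctrl_diag.copy()
    for s, v in patient_self.items():
        pat_diag[s] = v
    transmats = {"control": _self_transition_matrix(k_true, ctrl_diag),
                 "patient": _self_transition_matrix(k_true, pat_diag)}
    startprobs = {g: _stationary(tm) for g, tm in transmats.items()}

    if clinical_target_state is None:
        clinical_target_state = max(patient_self, key=patient_self.get) \
            if patient_self else 0
    spec = GenerativeSpec(
        k_true=k_true, atlas=atlas, means=means, covariances=covs,
        transmats=transmats, startprobs=startprobs,
        n_per_group=n_per_group, t_per_subject=t_per_subject,
        clinical_target_state=clinical_target_state,
        clinical_target_r=clinical_target_r, master_seed=master_seed)
    for name, value in field_overrides.items():
        if name not in GenerativeSpec.__dataclass_fields__:
            raise TypeError(f"unknown spec field: {name}")
        setattr(spec, name, value)
    spec.validate()
    return spec


def test_scale_spec(master_seed: int = 0, **overrides) -> GenerativeSpec:
    """Small spec (4 states, 10 ROIs over 3 networks, T=200, 20/group)
    that runs the full pipeline in seconds."""
    kw = dict(k_true=4, n_rois=10, n_networks=3, n_per_group=20,
              t_per_subject=200, master_seed=master_seed)
    kw.update(overrides)
    return build_spec(**kw)


def _sample_path(tm: np.ndarray, startprob: np.ndarray, t: int,
                 rng: np.random.Generator) -> np.ndarray:
    k = tm.shape[0]
    path = np.empty(t, dtype=int)
    cum_start = np.cumsum(startprob)
    cum_tm = np.cumsum(tm, axis=1)
    u = rng.random(t)
    path[0] = int(np.searchsorted(cum_start, u[0]))
    for i in range(1, t):
        path[i] = int(np.searchsorted(cum_tm[path[i - 1]], u[i]))
    return path


def _sample_fd(spec: GenerativeSpec, t: int,
               rng: np.random.Generator) -> np.ndarray:
    fd = np.abs(rng.normal(spec.fd_mean, spec.fd_sd, size=t))
    spikes = rng.random(t) < spec.fd_spike_prob
    lo, hi = spec.fd_spike_range
    fd[spikes] = rng.uniform(lo, hi, size=int(spikes.sum()))
    return fd


def simulate_subject(spec: GenerativeSpec, group: str, seed,
                     subject_id: str | None = None
                     ) -> tuple[SubjectTimeSeries, SubjectTruth]:
    """Sample one subject; bit-deterministic given (spec, group, seed)."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = spec.t_per_subject
    path = _sample_path(spec.transmats[group], spec.startprobs[group], t, rng)
    chols = np.linalg.cholesky(spec.covariances)
    z = rng.standard_normal((t, spec.n_rois))
    data = np.empty_like(z)
    for s in range(spec.k_true):
        mask = path == s
        if mask.any():
            data[mask] = spec.means[s] + z[mask] @ chols[s].T
    fd = _sample_fd(spec, t, rng)
    sid = subject_id or f"{group}_{seed}"
    ts = SubjectTimeSeries(subject_id=sid, group=group, data=data,
                           segments=[t], fd_trace=fd,
                           tr_seconds=spec.tr_seconds)
    return ts, SubjectTruth(subject_id=sid, group=group, path=path)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float | None, hi: float | None, size: int) -> np.ndarray:
    x = rng.normal(mean, sd, size=size)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def _sample_clinical(spec: GenerativeSpec, patient_ids: list[str],
                     target_mdt: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw clinical scores for patients; MIDAS is coupled to the true
    dwell time of the target state at correlation ``clinical_target_r``.

    The slope is calibrated against the realized dwell-time sample:
    with noise sd sigma = MIDAS_sd * sqrt(1 - r^2), beta =
    r * sigma / (sd(MDT) * sqrt(1 - r^2)) gives population correlation r
    before rounding/truncation (which attenuate it negligibly at these
    settings).
    """
    n = len(patient_ids)
    r = spec.clinical_target_r
    s_m = float(np.std(target_mdt, ddof=1)) if n > 1 else 0.0
    if r != 0 and s_m == 0:
        raise ValueError(
            "clinical coupling target unreachable: dwell time of the target"
            " state is constant across patients (feasible maximum r = 0)")
    sigma = _MIDAS_SD * float(np.sqrt(1 - r ** 2))
    beta = 0.0 if r == 0 else r * sigma / (s_m * float(np.sqrt(1 - r ** 2)))
    alpha = _MIDAS_MEAN - beta * float(np.mean(target_mdt))
    midas = np.maximum(
        0, np.round(alpha + beta * target_mdt + rng.normal(0, sigma, n)))
    clin = {"midas": midas.astype(float)}
    for col, (mean, sd, lo, hi) in _CLINICAL_MARGINALS.items():
        clin[col] = np.round(_truncnorm(rng, mean, sd, lo, hi, n), 1)
    clin["headache_days"] = rng.integers(1, 9, size=n).astype(float)
    return pd.DataFrame(clin, index=pd.Index(patient_ids,
                                             name="subject_id"))


def simulate_paths(spec: GenerativeSpec) -> GroundTruth:
    """State paths only (no emissions) — cheap cohort-level truth used for
    statistical calibration at many replicates."""
    spec.validate()
    truth = GroundTruth(spec=spec)
    counter = 0
    for group in ("control", "patient"):
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence((spec.master_seed, counter)))
            path = _sample_path(spec.transmats[group],
                                spec.startprobs[group],
                                spec.t_per_subject, rng)
            truth.subjects.append(SubjectTruth(
                subject_id=f"{group[:3]}{i + 1:03d}", group=group,
                path=path))
            counter += 1
    return truth


def simulate_clinical(spec: GenerativeSpec,
                      truth: GroundTruth) -> pd.DataFrame:
    """Clinical table for a simulated cohort (patients coupled, controls
    all-missing)."""
    patients = [s for s in truth.subjects if s.group == "patient"]
    target_mdt = np.array([
        mean_dwell_time(s.path, [len(s.path)], spec.k_true)[
            spec.clinical_target_state]
        for s in patients])
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.master_seed, 2 ** 20)))
    clin = _sample_clinical(spec, [s.subject_id for s in patients],
                            target_mdt, rng)
    controls = [s.subject_id for s in truth.subjects
                if s.group == "control"]
    empty = pd.DataFrame(np.nan, index=pd.Index(controls,
                                                name="subject_id"),
                         columns=clin.columns)
    return pd.concat([empty, clin])


def simulate_cohort(spec: GenerativeSpec
                    ) -> tuple[CohortDataset, GroundTruth]:
    """Full cohort: BOLD + FD traces + clinical table + ground truth."""
    spec.validate()
    truth = GroundTruth(spec=spec)
    subjects = []
    counter = 0
    for group in ("control", "patient"):
        for i in range(spec.n_per_group):
            sid = f"{group[:3]}{i + 1:03d}"
            ts, tr = simulate_subject(
                spec, group, (spec.master_seed, counter), subject_id=sid)
            subjects.append(ts)
            truth.subjects.append(tr)
            counter += 1
    clinical = simulate_clinical(spec, truth)
    cohort = CohortDataset(subjects=subjects, clinical=clinical,
                           atlas=spec.atlas)
    return cohort, truth
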