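"""Motion quality control, standardization, concatenation, static FC.

Quality control applies two subject-level exclusion rules — mean FD above
0.2 mm, or more than 20% of frames with FD above 0.5 mm — and, for
retained subjects, frame-level scrubbing: every frame with FD > 0.5 mm is
removed and the segment ledger is split at each removal, so no later stage
ever treats frames across a removed gap as temporally adjacent.

Standardization is per subject, per ROI column: subtract the mean and
divide by the population standard deviation (ddof = 0), giving exactly
mean 0 / SD 1 columns for the HMM.  Concatenation stacks all subjects'
segments into one matrix with a lengths ledger that confines transitions
within segments of one participant.

Static functional connectivity is the all-frames Pearson correlation
matrix, Fisher z-transformed (r clipped to |r| <= 1 - 1e-7 first, since
atanh(+-1) diverges) with a zero diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import CohortDataset, SubjectTimeSeries, ValidationError

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7


@dataclass
class ScrubResult:
    """Outcome of QC for one subject: a retained (possibly scrubbed)
    subject, or an exclusion with its reason."""

    subject: SubjectTimeSeries | None
    excluded: bool
    reason: str | None = None


def _split_mask_into_segments(keep: np.ndarray,
                              segments: list[int]) -> list[int]:
    """New segment lengths: contiguous retained runs within old segments."""
    out: list[int] = []
    start = 0
    for ln in segments:
        seg_keep = keep[start:start + ln]
        run = 0
        for k in seg_keep:
            if k:
                run += 1
            elif run:
                out.append(run)
                run = 0
        if run:
            out.append(run)
        start += ln
    return out


def qc_and_scrub(ts: SubjectTimeSeries, mean_fd_max: float = 0.2,
                 spike_fd: float = 0.5,
                 spike_frac_max: float = 0.2) -> ScrubResult:
    """Apply motion exclusion rules, then scrub spike frames.

    Subjects without an FD trace pass through unchanged (with a warning):
    motion cannot be assessed, so nothing is removed.
    """
    if ts.fd_trace is None:
        logger.warning("subject %s: no FD trace; QC skipped", ts.subject_id)
        return ScrubResult(subject=ts, excluded=False)
    fd = ts.fd_trace
    mean_fd = float(fd.mean())
    spike_frac = float(np.mean(fd > spike_fd))
    if mean_fd > mean_fd_max:
        return ScrubResult(subject=None, excluded=True,
                           reason=f"mean FD {mean_fd:.4f} mm > "
                                  f"{mean_fd_max} mm")
    if spike_frac > spike_frac_max:
        return ScrubResult(subject=None, excluded=True,
                           reason=f"{spike_frac:.1%} of frames with FD > "
                                  f"{spike_fd} mm (limit "
                                  f"{spike_frac_max:.0%})")
    keep = fd <= spike_fd
    if keep.all():
        return ScrubResult(subject=ts, excluded=False)
    new_segments = _split_mask_into_segments(keep, ts.segments)
    scrubbed = SubjectTimeSeries(
        subject_id=ts.subject_id, group=ts.group, data=ts.data[keep],
        segments=new_segments, fd_trace=fd[keep], tr_seconds=ts.tr_seconds)
    return ScrubResult(subject=scrubbed, excluded=False)


def zscore(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Column-wise z-standardization with population SD (ddof = 0)."""
    mean = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        raise ValidationError(
            f"subject {ts.subject_id}: zero-variance ROI column(s) "
            f"{zero.tolist()}")
    return SubjectTimeSeries(
        subject_id=ts.subject_id, group=ts.group,
        data=(ts.data - mean) / sd, segments=list(ts.segments),
        fd_trace=ts.fd_trace, tr_seconds=ts.tr_seconds)


@dataclass
class ConcatenatedSeries:
    """All subjects' z-scored data stacked with a segment ledger."""

    data: np.ndarray               # (sum T_s) x N
    lengths: list[int]             # per-segment lengths, in row order
    segment_owner: list[str]       # subject id per segment
    subject_segments: dict[str, list[int]] = field(default_factory=dict)
    subject_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.lengths) != self.data.shape[0]:
            raise ValidationError("lengths ledger does not match row count")
        if len(self.lengths) != len(self.segment_owner):
            raise ValidationError("one owner per segment required")

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for sid in self.segment_owner:
            if sid not in seen:
                seen.append(sid)
        return seen

    def rows_for_subject(self, subject_id: str) -> np.ndarray:
        """Row indices of all of one subject's frames, in temporal order."""
        idx = []
        start = 0
        for ln, owner in zip(self.lengths, self.segment_owner):
            if owner == subject_id:
                idx.append(np.arange(start, start + ln))
            start += ln
        if not idx:
            raise KeyError(subject_id)
        return np.concatenate(idx)


def concatenate(cohort: CohortDataset) -> ConcatenatedSeries:
    """Stack subjects in manifest order, segments in temporal order."""
    blocks, lengths, owners = [], [], []
    subject_segments: dict[str, list[int]] = {}
    subject_group: dict[str, str] = {}
    for s in cohort.subjects:
        blocks.append(s.data)
        lengths.extend(s.segments)
        owners.extend([s.subject_id] * len(s.segments))
        subject_segments[s.subject_id] = list(s.segments)
        subject_group[s.subject_id] = s.group
    return ConcatenatedSeries(data=np.vstack(blocks), lengths=lengths,
                              segment_owner=owners,
                              subject_segments=subject_segments,
                              subject_group=subject_group)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping at |r| = 1 - 1e-7 to keep values finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def static_fc(ts: SubjectTimeSeries) -> np.ndarray:
    """Whole-scan Pearson FC, Fisher z-transformed, zero diagonal."""
    if ts.n_frames < 3:
        raise ValidationError(
            f"subject {ts.subject_id}: need T >= 3 frames for FC")
    sd = ts.data.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        raise ValidationError(
            f"subject {ts.subject_id}: zero-variance ROI column(s) "
            f"{zero.tolist()}")
    r = np.corrcoef(ts.data, rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return z
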