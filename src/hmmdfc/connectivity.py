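"""State-wise functional connectivity from state-assigned frames.

For each (subject, state) pair the frames hard-assigned to the state by
the Viterbi path are pooled across all of the subject's segments
(covariance needs no temporal ordering) and, when at least ``min_frames``
frames (default 30) are available, a Ledoit-Wolf shrinkage covariance is
estimated, converted to a correlation matrix, Fisher z-transformed (with
the same |r| <= 1 - 1e-7 clipping as static FC) and its diagonal zeroed.
Pairs under the frame threshold are marked missing and carry only their
frame count; group statistics later use available matrices only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from .hmm import StateSequence
from .prep import fisher_z
from .types import ValidationError

MIN_FRAMES_DEFAULT = 30


def state_frames(seq: StateSequence, state: int) -> np.ndarray:
    """Frame indices the Viterbi path assigns to ``state``."""
    return np.flatnonzero(np.asarray(seq.viterbi) == state)


@dataclass
class StateFCEntry:
    subject_id: str
    state: int
    n_frames: int
    matrix: np.ndarray | None      # N x N Fisher-z, or None when missing
    shrinkage: float | None = None

    @property
    def present(self) -> bool:
        return self.matrix is not None


def state_fc(data: np.ndarray, frames: np.ndarray,
             min_frames: int = MIN_FRAMES_DEFAULT
             ) -> tuple[np.ndarray | None, float | None]:
    """Shrunk, z-transformed connectivity over the given frames.

    Returns ``(matrix, shrinkage_intensity)`` or ``(None, None)`` when
    fewer than ``min_frames`` frames are available.
    """
    frames = np.asarray(frames, dtype=int)
    if frames.size < min_frames:
        return None, None
    sub = np.asarray(data, dtype=float)[frames]
    sd = sub.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        raise ValidationError(
            f"zero-variance ROI column(s) within state frames: "
            f"{zero.tolist()}")
    lw = LedoitWolf(assume_centered=False).fit(sub)
    cov = lw.covariance_
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    z = fisher_z(corr)
    np.fill_diagonal(z, 0.0)
    return z, float(lw.shrinkage_)


def compute_state_fc_set(data_by_subject: dict[str, np.ndarray],
                         sequences: dict[str, StateSequence],
                         n_states: int,
                         min_frames: int = MIN_FRAMES_DEFAULT
                         ) -> list[StateFCEntry]:
    """All (subject, state) connectivity matrices with availability."""
    entries = []
    for sid, seq in sequences.items():
        data = data_by_subject[sid]
        for state in range(n_states):
            frames = state_frames(seq, state)
            matrix, shrink = state_fc(data, frames, min_frames=min_frames)
            entries.append(StateFCEntry(
                subject_id=sid, state=state, n_frames=int(frames.size),
                matrix=matrix, shrinkage=shrink))
    return entries


def availability_table(entries: list[StateFCEntry]) -> pd.DataFrame:
    """(subject, state, n_frames, present, shrinkage) — states 1-based."""
    return pd.DataFrame([{
        "subject_id": e.subject_id, "state": e.state + 1,
        "n_frames": e.n_frames, "present": e.present,
        "shrinkage": e.shrinkage if e.present else np.nan,
    } for e in entries])


def group_mean_state_fc(entries: list[StateFCEntry],
                        groups: dict[str, str], state: int,
                        group: str) -> np.ndarray | None:
    """Mean z-matrix over a group's subjects with the state present."""
    mats = [e.matrix for e in entries
            if e.state == state and e.present
            and groups[e.subject_id] == group]
    if not mats:
        return None
    return np.mean(np.stack(mats), axis=0)
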