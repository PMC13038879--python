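"""Per-subject temporal state metrics.

Fractional occupancy (FO) is computed from the soft posteriors gamma(t, k):
FO_k = mean_t gamma(t, k).  Mean dwell time (MDT), switching rate,
transition counts and the individual transition probability matrix (TPM)
are computed from the hard Viterbi path.  All run/transition bookkeeping is
segment-local: a removed-frame gap or a subject boundary never merges runs
and never contributes a transition pair.

MDT is in TR units (multiply by ``tr_seconds`` for seconds).  States a
subject never visits get NaN dwell time and are excluded from group
statistics; TPM rows with no outgoing transition are left as zero rows and
flagged via ``empty_rows``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def split_segments(path: np.ndarray, segments: list[int]) -> list[np.ndarray]:
    """Cut a concatenated state path into its continuous segments."""
    path = np.asarray(path)
    if sum(segments) != path.shape[0]:
        raise ValueError("segments do not sum to path length")
    out, start = [], 0
    for ln in segments:
        out.append(path[start:start + ln])
        start += ln
    return out


def run_lengths(path: np.ndarray, segments: list[int]) -> list[tuple[int, int]]:
    """(state, length) for every maximal constant run within a segment."""
    runs: list[tuple[int, int]] = []
    for seg in split_segments(path, segments):
        if seg.size == 0:
            continue
        change = np.flatnonzero(np.diff(seg) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [seg.size]))
        runs.extend((int(seg[s]), int(e - s)) for s, e in zip(starts, ends))
    return runs


def fractional_occupancy(gamma: np.ndarray) -> np.ndarray:
    """FO_k = (1/T) sum_t gamma(t, k); sums to 1 when gamma rows do."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2:
        raise ValueError("gamma must be T x K")
    return gamma.mean(axis=0)


def mean_dwell_time(path: np.ndarray, segments: list[int],
                    n_states: int) -> np.ndarray:
    """Mean length (TRs) of a subject's visits to each state; NaN if never
    visited."""
    mdt = np.full(n_states, np.nan)
    runs = run_lengths(path, segments)
    for k in range(n_states):
        lens = [ln for s, ln in runs if s == k]
        if lens:
            mdt[k] = float(np.mean(lens))
    return mdt


def switching_rate(path: np.ndarray, segments: list[int]) -> float:
    """Fraction of within-segment consecutive frame pairs that change state.

    NaN when every segment has length 1 (no pairs at all).
    """
    changes = 0
    pairs = 0
    for seg in split_segments(path, segments):
        pairs += max(seg.size - 1, 0)
        changes += int(np.count_nonzero(np.diff(seg) != 0))
    return changes / pairs if pairs > 0 else float("nan")


def transition_counts(path: np.ndarray, segments: list[int],
                      n_states: int) -> np.ndarray:
    """K x K counts of directed within-segment transitions, self-transitions
    included; totals Sum(len - 1) over segments."""
    counts = np.zeros((n_states, n_states), dtype=int)
    for seg in split_segments(path, segments):
        if seg.size >= 2:
            np.add.at(counts, (seg[:-1], seg[1:]), 1)
    return counts


def subject_tpm(path: np.ndarray, segments: list[int],
                n_states: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-normalized transition counts.

    Returns ``(counts, tpm, empty_rows)``; rows with zero outgoing
    transitions stay all-zero and are flagged in ``empty_rows``.
    """
    counts = transition_counts(path, segments, n_states)
    totals = counts.sum(axis=1)
    tpm = np.zeros((n_states, n_states), dtype=float)
    nonzero = totals > 0
    tpm[nonzero] = counts[nonzero] / totals[nonzero, None]
    return counts, tpm, ~nonzero


@dataclass
class SubjectDynamics:
    """All temporal metrics for one subject."""

    subject_id: str
    group: str
    fo: np.ndarray
    mdt: np.ndarray
    switching_rate: float
    transition_counts: np.ndarray
    tpm: np.ndarray
    empty_tpm_rows: np.ndarray = field(default=None)  # type: ignore


def compute_subject_dynamics(subject_id: str, group: str,
                             viterbi: np.ndarray, gamma: np.ndarray,
                             segments: list[int],
                             n_states: int) -> SubjectDynamics:
    counts, tpm, empty = subject_tpm(viterbi, segments, n_states)
    return SubjectDynamics(
        subject_id=subject_id,
        group=group,
        fo=fractional_occupancy(gamma),
        mdt=mean_dwell_time(viterbi, segments, n_states),
        switching_rate=switching_rate(viterbi, segments),
        transition_counts=counts,
        tpm=tpm,
        empty_tpm_rows=empty,
    )


def group_mean_tpm(tpms: list[np.ndarray],
                   empty_rows: list[np.ndarray] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cell-wise mean TPM across subjects.

    A subject's flagged-empty row is skipped (does not dilute the mean);
    the per-row number of contributing subjects is returned.  A row no
    subject contributes becomes NaN.
    """
    if not tpms:
        raise ValueError("need at least one subject TPM")
    stack = np.stack([np.asarray(t, dtype=float) for t in tpms])
    n_sub, k, _ = stack.shape
    if empty_rows is None:
        empty_rows = [np.zeros(k, dtype=bool)] * n_sub
    mask = np.stack([~np.asarray(e, dtype=bool) for e in empty_rows])  # S x K
    contrib = mask.sum(axis=0).astype(float)                           # K
    weighted = np.where(mask[:, :, None], stack, 0.0).sum(axis=0)
    mean = np.full((k, k), np.nan)
    rows = contrib > 0
    mean[rows] = weighted[rows] / contrib[rows, None]
    return mean, contrib.astype(int)


def dynamics_tables(dyns: list[SubjectDynamics],
                    tr_seconds: float = 2.0) -> dict[str, pd.DataFrame]:
    """Long-format TSV-ready tables (states rendered 1-based)."""
    k = dyns[0].fo.shape[0]
    fo_rows, mdt_rows, sw_rows = [], [], []
    for d in dyns:
        sw_rows.append({"subject_id": d.subject_id, "group": d.group,
                        "switching_rate": d.switching_rate})
        for s in range(k):
            fo_rows.append({"subject_id": d.subject_id, "group": d.group,
                            "state": s + 1, "fo": d.fo[s]})
            mdt_rows.append({"subject_id": d.subject_id, "group": d.group,
                             "state": s + 1, "mdt_tr": d.mdt[s],
                             "mdt_seconds": d.mdt[s] * tr_seconds})
    return {"fo": pd.DataFrame(fo_rows),
            "mdt": pd.DataFrame(mdt_rows),
            "switching": pd.DataFrame(sw_rows)}
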