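"""Core data model shared by every pipeline stage.

The atom of the pipeline is a per-subject ROI x time BOLD matrix together
with its motion trace and a ledger of continuous segment lengths.  The
segment ledger exists because motion scrubbing removes individual frames:
every temporal computation downstream (HMM transitions, dwell times,
switching) must treat frames on either side of a removed gap as
non-adjacent, and concatenation across subjects must never let a state
transition span two people.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven canonical large-scale networks: visual, somatomotor, dorsal
#: attention, ventral attention/salience, subcortical, frontoparietal,
#: default mode.
CANONICAL_NETWORKS = ("VN", "SMN", "DAN", "VAN", "SC", "FPN", "DMN")

#: Group labels for the two-arm cohort.
GROUPS = ("control", "patient")

#: Clinical columns carried in the manifest; controls may have all missing.
CLINICAL_COLUMNS = ("vas", "hit6", "midas", "sds", "duration_years",
                    "headache_days")

_CLINICAL_BOUNDS = {
    "vas": (0.0, 10.0),
    "hit6": (36.0, 78.0),
    "midas": (0.0, None),
    "sds": (20.0, None),
    "duration_years": (0.0, None),
    "headache_days": (0.0, None),
}


class ValidationError(ValueError):
    """Raised when an on-disk artifact or in-memory object violates an
    invariant of the data model."""


@dataclass
class AtlasMapping:
    """ROI -> network assignment for an N-ROI parcellation.

    ``roi_names[i]`` and ``networks[i]`` describe ROI index ``i`` (0-based,
    contiguous).  Every ROI belongs to exactly one network drawn from
    :data:`CANONICAL_NETWORKS`; the default cortical+subcortical atlas has
    N = 142 ROIs over all seven networks, but reduced atlases (fewer ROIs,
    a subset of networks) are valid for simulation and testing.
    """

    roi_names: list[str]
    networks: list[str]

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(self.networks):
            raise ValidationError(
                "atlas roi_names and networks differ in length")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValidationError("atlas ROI names are not unique")
        bad = sorted(set(self.networks) - set(CANONICAL_NETWORKS))
        if bad:
            raise ValidationError(f"unknown network label(s): {bad}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def network_names(self) -> list[str]:
        """Networks present in this atlas, in canonical order."""
        present = set(self.networks)
        return [n for n in CANONICAL_NETWORKS if n in present]

    def rois_in_network(self, network: str) -> np.ndarray:
        """0-based ROI indices belonging to ``network``."""
        return np.array([i for i, n in enumerate(self.networks)
                         if n == network], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi_index": np.arange(self.n_rois),
            "roi_name": self.roi_names,
            "network": self.networks,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AtlasMapping":
        required = {"roi_index", "roi_name", "network"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"atlas table needs columns {sorted(required)}")
        df = df.sort_values("roi_index")
        idx = df["roi_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(df))):
            raise ValidationError(
                "atlas roi_index values must be contiguous 0..N-1")
        return cls(roi_names=[str(x) for x in df["roi_name"]],
                   networks=[str(x) for x in df["network"]])


@dataclass
class SubjectTimeSeries:
    """One subject's ROI time series with motion trace and segment ledger.

    Parameters
    ----------
    data : (T, N) array
        BOLD values, one row per retained volume, one column per ROI.
    segments : list of int
        Lengths of continuous runs of frames, in temporal order; they sum
        to T.  A fresh (unscrubbed) subject has one segment of length T.
    fd_trace : (T,) array, optional
        Framewise displacement in millimetres, aligned with ``data`` rows.
    """

    subject_id: str
    group: str
    data: np.ndarray
    segments: list[int] = field(default_factory=list)
    fd_trace: np.ndarray | None = None
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"subject {self.subject_id}: data must be T x N")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(
                f"subject {self.subject_id}: non-finite values in data")
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r}")
        if not self.segments:
            self.segments = [self.data.shape[0]]
        if any(s < 1 for s in self.segments):
            raise ValidationError(
                f"subject {self.subject_id}: segment of length < 1")
        if sum(self.segments) != self.data.shape[0]:
            raise ValidationError(
                f"subject {self.subject_id}: segments sum to "
                f"{sum(self.segments)} but data has {self.data.shape[0]} rows")
        if self.fd_trace is not None:
            self.fd_trace = np.asarray(self.fd_trace, dtype=float)
            if self.fd_trace.shape != (self.data.shape[0],):
                raise ValidationError(
                    f"subject {self.subject_id}: fd_trace length "
                    f"{self.fd_trace.shape[0]} != T {self.data.shape[0]}")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-subject clinical table (index = subject_id).

    Missing values are allowed everywhere (controls typically have none of
    the scores); present values must respect the scale ranges, e.g. VAS in
    0-10 and HIT-6 in 36-78.
    """
    if clinical.index.has_duplicates:
        raise ValidationError("duplicate subject ids in clinical table")
    for col in CLINICAL_COLUMNS:
        if col not in clinical.columns:
            clinical[col] = np.nan
        vals = pd.to_numeric(clinical[col], errors="coerce")
        lo, hi = _CLINICAL_BOUNDS[col]
        present = vals.dropna()
        if lo is not None and (present < lo).any():
            raise ValidationError(f"clinical column {col}: value below {lo}")
        if hi is not None and (present > hi).any():
            raise ValidationError(f"clinical column {col}: value above {hi}")
        clinical[col] = vals
    return clinical[list(CLINICAL_COLUMNS)]


@dataclass
class CohortDataset:
    """A validated two-group cohort: subjects + clinical table + atlas."""

    subjects: list[SubjectTimeSeries]
    clinical: pd.DataFrame
    atlas: AtlasMapping

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in cohort")
        for s in self.subjects:
            if s.n_rois != self.atlas.n_rois:
                raise ValidationError(
                    f"subject {s.subject_id}: {s.n_rois} ROI columns, atlas "
                    f"has {self.atlas.n_rois}")
        self.clinical = validate_clinical(self.clinical.copy())
        missing = set(self.clinical.index) - set(ids)
        if missing:
            raise ValidationError(
                f"clinical rows without a matching subject: {sorted(missing)}")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subjects_in_group(self, group: str) -> list[SubjectTimeSeries]:
        return [s for s in self.subjects if s.group == group]
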