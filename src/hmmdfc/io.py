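"""Reading and writing every on-disk artifact.

All tables are tab-separated UTF-8 text with a single header line and "."
as the decimal mark.  Floats are written with ``repr`` (shortest
round-trip) precision, so write -> read reproduces matrices exactly.

Layout of a cohort directory::

    manifest.tsv        subject_id, group, timeseries_path, [fd_path,]
                        [segments,] vas, hit6, midas, sds, duration_years,
                        headache_days
    atlas.tsv           roi_index, roi_name, network
    timeseries/<id>.tsv one header line of ROI names, then T rows x N cols
    fd/<id>.tsv         single column "fd", T rows (optional)

ROI ordering is authoritative from the atlas file; a time-series header
that disagrees with it is an error, never silently reordered.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import (AtlasMapping, CohortDataset, SubjectTimeSeries,
                    CLINICAL_COLUMNS, GROUPS, ValidationError)

SEP = "\t"


def read_atlas(path: str | Path) -> AtlasMapping:
    df = pd.read_csv(path, sep=SEP)
    return AtlasMapping.from_frame(df)


def write_atlas(atlas: AtlasMapping, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep=SEP, index=False)


def _read_timeseries(path: Path, atlas: AtlasMapping,
                     subject_id: str) -> np.ndarray:
    if not path.exists():
        raise ValidationError(
            f"subject {subject_id}: time-series file not found: {path}")
    df = pd.read_csv(path, sep=SEP, float_precision="round_trip")
    if df.shape[1] != atlas.n_rois:
        raise ValidationError(
            f"subject {subject_id}: {df.shape[1]} ROI columns in {path.name},"
            f" atlas has {atlas.n_rois}")
    if list(df.columns) != atlas.roi_names:
        raise ValidationError(
            f"subject {subject_id}: ROI header order in {path.name} does not"
            " match the atlas")
    return df.to_numpy(dtype=float)


def read_cohort(manifest_path: str | Path,
                atlas_path: str | Path) -> CohortDataset:
    """Load a cohort from a manifest + atlas pair.

    Time-series (and optional FD) paths in the manifest are resolved
    relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    atlas = read_atlas(atlas_path)
    mf = pd.read_csv(manifest_path, sep=SEP, dtype={"subject_id": str},
                     float_precision="round_trip")
    required = {"subject_id", "group", "timeseries_path"}
    if not required.issubset(mf.columns):
        raise ValidationError(f"manifest needs columns {sorted(required)}")

    subjects = []
    for _, row in mf.iterrows():
        sid = str(row["subject_id"])
        group = str(row["group"])
        if group not in GROUPS:
            raise ValidationError(
                f"subject {sid}: unknown group label {group!r}")
        data = _read_timeseries(base / str(row["timeseries_path"]),
                                atlas, sid)
        fd = None
        if "fd_path" in mf.columns and isinstance(row.get("fd_path"), str) \
                and row["fd_path"].strip():
            fd_df = pd.read_csv(base / row["fd_path"], sep=SEP,
                                float_precision="round_trip")
            fd = fd_df["fd"].to_numpy(dtype=float)
        segments = None
        if "segments" in mf.columns and not pd.isna(row.get("segments")):
            segments = [int(x) for x in str(row["segments"]).split(",")]
        subjects.append(SubjectTimeSeries(
            subject_id=sid, group=group, data=data,
            segments=segments or [data.shape[0]], fd_trace=fd,
            tr_seconds=float(row.get("tr_seconds", 2.0))
            if "tr_seconds" in mf.columns else 2.0))

    clin_cols = [c for c in CLINICAL_COLUMNS if c in mf.columns]
    clinical = mf.set_index("subject_id")[clin_cols] if clin_cols \
        else pd.DataFrame(index=mf["subject_id"])
    return CohortDataset(subjects=subjects, clinical=clinical, atlas=atlas)


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort directory; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "timeseries").mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out_dir / "atlas.tsv")
    has_fd = any(s.fd_trace is not None for s in cohort.subjects)
    if has_fd:
        (out_dir / "fd").mkdir(exist_ok=True)

    rows = []
    for s in cohort.subjects:
        ts_rel = f"timeseries/{s.subject_id}.tsv"
        pd.DataFrame(s.data, columns=cohort.atlas.roi_names).to_csv(
            out_dir / ts_rel, sep=SEP, index=False)
        row: dict = {"subject_id": s.subject_id, "group": s.group,
                     "timeseries_path": ts_rel,
                     "segments": ",".join(str(x) for x in s.segments),
                     "tr_seconds": s.tr_seconds}
        if s.fd_trace is not None:
            fd_rel = f"fd/{s.subject_id}.tsv"
            pd.DataFrame({"fd": s.fd_trace}).to_csv(
                out_dir / fd_rel, sep=SEP, index=False)
            row["fd_path"] = fd_rel
        for col in CLINICAL_COLUMNS:
            row[col] = cohort.clinical.loc[s.subject_id, col] \
                if s.subject_id in cohort.clinical.index else np.nan
        rows.append(row)
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep=SEP, index=False)
    return manifest


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  run_info: Mapping | None = None) -> list[Path]:
    """Write named result tables as TSV plus a structured run manifest.

    ``tables`` maps a base name (e.g. ``"fo"``) to a DataFrame; each is
    written to ``<out_dir>/<name>.tsv``.  ``run_info`` (settings, seeds)
    is serialized to ``run_manifest.json`` with library versions attached.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep=SEP, index=False)
        written.append(path)
    manifest = dict(run_info or {})
    manifest["versions"] = _versions()
    manifest["tables"] = sorted(f"{n}.tsv" for n in tables)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(path)
    return written


def _versions() -> dict:
    import hmmlearn
    import scipy
    import sklearn
    import statsmodels
    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "hmmlearn": hmmlearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_matrix(matrix: np.ndarray, path: str | Path,
                 labels: Iterable[str] | None = None) -> None:
    """Write a square matrix as TSV with row/column labels."""
    matrix = np.asarray(matrix)
    labels = list(labels) if labels is not None else [
        str(i + 1) for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, sep=SEP, index_label="")


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep=SEP, index_col=0,
                       float_precision="round_trip").to_numpy(dtype=float)
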