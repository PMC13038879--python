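"""End-to-end orchestration of the brain-state analysis.

Stage order (each stage reads the previous stage's on-disk artifacts, so
any suffix of the chain can be rerun against an existing output
directory)::

    prep          QC/scrub + z-score + write prepped cohort, exclusions
    select        K grid search with restarts -> selection.tsv, model.json
    decode        Viterbi + posteriors -> viterbi.tsv, gamma/<id>.tsv
    metrics       FO/MDT/switching/TPMs -> fo.tsv, mdt.tsv, switching.tsv,
                  tpm_subject_<id>.tsv, tpm_group_<grp>.tsv
    connectivity  state-wise Ledoit-Wolf FC -> state_fc_<id>_<k>.tsv,
                  state_fc_availability.tsv
    netload       High/Neutral/Low table -> network_load.tsv
    stats         metric + transition + edge families -> stats_*.tsv
    correlate     clinical correlations -> correlations.tsv

Requesting a stage whose inputs are absent raises a dependency error
naming the stage to run first.  All randomness flows from
``RunConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics as dyn
from . import hmm as hmm_mod
from . import io as io_mod
from . import network_load as nl
from . import prep as prep_mod
from .connectivity import (StateFCEntry, availability_table,
                           compute_state_fc_set)
from . import stats as stats_mod
from .types import CohortDataset, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("prep", "select", "decode", "metrics", "connectivity",
          "netload", "stats", "correlate")


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass
class RunConfig:
    """All tunable settings of a pipeline run."""

    seed: int = 0
    # motion QC
    mean_fd_max: float = 0.2
    spike_fd: float = 0.5
    spike_frac_max: float = 0.2
    # model selection / fitting
    k_min: int = 2
    k_max: int = 14
    fixed_k: int | None = None
    n_seeds: int = 10
    max_iter: int = 500
    tol: float = 1e-4
    pca_components: int | None = None
    # metrics / connectivity
    min_frames: int = 30
    neutral_band: float = 0.10
    fo_source: str = "gamma"          # "gamma" | "viterbi"
    netload_source: str = "group_fc"  # "group_fc" | "model"
    # statistics
    alpha: float = 0.05
    q_threshold: float = 0.05
    # simulation block (passed through to synthetic.build_spec)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.k_max < cfg.k_min:
            raise ValidationError("empty K grid (k_max < k_min)")
        for name in ("mean_fd_max", "spike_fd", "spike_frac_max",
                     "min_frames", "neutral_band", "alpha", "q_threshold"):
            if getattr(cfg, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if cfg.fo_source not in ("gamma", "viterbi"):
            raise ValidationError("fo_source must be gamma or viterbi")
        if cfg.netload_source not in ("group_fc", "model"):
            raise ValidationError("netload_source must be group_fc or "
                                  "model")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path.name}: run stage '{producer}' first")
    return path


def _load_prepped(out_dir: Path) -> CohortDataset:
    manifest = _require(out_dir / "prepped" / "manifest.tsv", "prep")
    return io_mod.read_cohort(manifest, out_dir / "prepped" / "atlas.tsv")


def _load_sequences(out_dir: Path, cohort: CohortDataset
                    ) -> dict[str, hmm_mod.StateSequence]:
    vit_path = _require(out_dir / "viterbi.tsv", "decode")
    vit = pd.read_csv(vit_path, sep="\t", dtype={"subject_id": str})
    seqs = {}
    for sid, grp in vit.groupby("subject_id", sort=False):
        gamma = pd.read_csv(
            _require(out_dir / "gamma" / f"{sid}.tsv", "decode"),
            sep="\t").to_numpy(float)
        seqs[str(sid)] = hmm_mod.StateSequence(
            subject_id=str(sid),
            viterbi=grp.sort_values("t")["state"].to_numpy(int) - 1,
            gamma=gamma)
    return seqs


def stage_prep(cohort: CohortDataset, config: RunConfig,
               out_dir: Path) -> CohortDataset:
    kept, exclusions = [], []
    for s in cohort.subjects:
        res = prep_mod.qc_and_scrub(
            s, mean_fd_max=config.mean_fd_max, spike_fd=config.spike_fd,
            spike_frac_max=config.spike_frac_max)
        if res.excluded:
            exclusions.append({"subject_id": s.subject_id,
                               "reason": res.reason})
            continue
        kept.append(prep_mod.zscore(res.subject))
    logger.info("prep: %d subjects retained, %d excluded",
                len(kept), len(exclusions))
    if not kept:
        raise ValidationError("every subject was excluded by motion QC")
    prepped = CohortDataset(
        subjects=kept,
        clinical=cohort.clinical.loc[
            cohort.clinical.index.intersection(
                [s.subject_id for s in kept])],
        atlas=cohort.atlas)
    io_mod.write_cohort(prepped, out_dir / "prepped")
    pd.DataFrame(exclusions, columns=["subject_id", "reason"]).to_csv(
        out_dir / "exclusions.tsv", sep="\t", index=False)
    return prepped


def stage_select(config: RunConfig, out_dir: Path
                 ) -> hmm_mod.GaussianHMMModel:
    cohort = _load_prepped(out_dir)
    x = prep_mod.concatenate(cohort)
    proj = None
    if config.pca_components and x.n_rois > config.pca_components:
        from sklearn.decomposition import PCA
        pca = PCA(n_components=config.pca_components, svd_solver="full")
        data = pca.fit_transform(x.data)
        proj = pca.components_
        x = prep_mod.ConcatenatedSeries(
            data=data, lengths=list(x.lengths),
            segment_owner=list(x.segment_owner),
            subject_segments=dict(x.subject_segments),
            subject_group=dict(x.subject_group))
    if config.fixed_k is not None:
        sel = hmm_mod.select_k(
            x, k_min=config.fixed_k, k_max=config.fixed_k,
            n_seeds=config.n_seeds, master_seed=config.seed,
            max_iter=config.max_iter, tol=config.tol)
    else:
        sel = hmm_mod.select_k(
            x, k_min=config.k_min, k_max=config.k_max,
            n_seeds=config.n_seeds, master_seed=config.seed,
            max_iter=config.max_iter, tol=config.tol)
    sel.table.to_csv(out_dir / "selection.tsv", sep="\t", index=False)
    model = sel.models[sel.chosen_k]
    model.to_json(out_dir / "model.json")
    if proj is not None:
        np.savetxt(out_dir / "pca_projection.tsv", proj, delimiter="\t")
    return model


def stage_decode(config: RunConfig, out_dir: Path
                 ) -> dict[str, hmm_mod.StateSequence]:
    cohort = _load_prepped(out_dir)
    model = hmm_mod.GaussianHMMModel.from_json(
        _require(out_dir / "model.json", "select"))
    x = prep_mod.concatenate(cohort)
    proj_path = out_dir / "pca_projection.tsv"
    if proj_path.exists():
        proj = np.loadtxt(proj_path, delimiter="\t", ndmin=2)
        x = prep_mod.ConcatenatedSeries(
            data=(x.data - x.data.mean(axis=0)) @ proj.T,
            lengths=list(x.lengths),
            segment_owner=list(x.segment_owner),
            subject_segments=dict(x.subject_segments),
            subject_group=dict(x.subject_group))
    seqs = hmm_mod.decode(model, x)
    (out_dir / "gamma").mkdir(exist_ok=True)
    rows = []
    for s in cohort.subjects:
        seq = seqs[s.subject_id]
        for t, st in enumerate(seq.viterbi):
            rows.append((s.subject_id, t, int(st) + 1))
        pd.DataFrame(seq.gamma,
                     columns=[f"S{k + 1}" for k in range(model.k)]
                     ).to_csv(out_dir / "gamma" / f"{s.subject_id}.tsv",
                              sep="\t", index=False)
    pd.DataFrame(rows, columns=["subject_id", "t", "state"]).to_csv(
        out_dir / "viterbi.tsv", sep="\t", index=False)
    return seqs


def stage_metrics(config: RunConfig, out_dir: Path
                  ) -> list[dyn.SubjectDynamics]:
    cohort = _load_prepped(out_dir)
    seqs = _load_sequences(out_dir, cohort)
    k = next(iter(seqs.values())).gamma.shape[1]
    dyns = []
    for s in cohort.subjects:
        seq = seqs[s.subject_id]
        gamma = np.eye(k)[seq.viterbi] if config.fo_source == "viterbi" \
            else seq.gamma
        dyns.append(dyn.compute_subject_dynamics(
            s.subject_id, s.group, seq.viterbi, gamma, s.segments, k))
    tables = dyn.dynamics_tables(
        dyns, tr_seconds=cohort.subjects[0].tr_seconds)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    labels = [f"S{i + 1}" for i in range(k)]
    for d in dyns:
        io_mod.write_matrix(d.tpm, out_dir / f"tpm_subject_{d.subject_id}.tsv",
                            labels)
    for group in ("control", "patient"):
        sub = [d for d in dyns if d.group == group]
        if sub:
            mean, _ = dyn.group_mean_tpm([d.tpm for d in sub],
                                         [d.empty_tpm_rows for d in sub])
            io_mod.write_matrix(mean, out_dir / f"tpm_group_{group}.tsv",
                                labels)
    return dyns


def stage_connectivity(config: RunConfig, out_dir: Path
                       ) -> list[StateFCEntry]:
    cohort = _load_prepped(out_dir)
    seqs = _load_sequences(out_dir, cohort)
    k = next(iter(seqs.values())).gamma.shape[1]
    data = {s.subject_id: s.data for s in cohort.subjects}
    entries = compute_state_fc_set(data, seqs, k,
                                       min_frames=config.min_frames)
    availability_table(entries).to_csv(
        out_dir / "state_fc_availability.tsv", sep="\t", index=False)
    fc_dir = out_dir / "state_fc"
    fc_dir.mkdir(exist_ok=True)
    for e in entries:
        if e.present:
            io_mod.write_matrix(
                e.matrix, fc_dir / f"state_fc_{e.subject_id}_S{e.state + 1}.tsv",
                cohort.atlas.roi_names)
    return entries


def _reload_entries(out_dir: Path, cohort: CohortDataset
                    ) -> list[StateFCEntry]:
    avail = pd.read_csv(
        _require(out_dir / "state_fc_availability.tsv", "connectivity"),
        sep="\t", dtype={"subject_id": str})
    entries = []
    for _, row in avail.iterrows():
        matrix = None
        if row["present"]:
            matrix = io_mod.read_matrix(
                out_dir / "state_fc" /
                f"state_fc_{row['subject_id']}_S{row['state']}.tsv")
        entries.append(StateFCEntry(
            subject_id=str(row["subject_id"]),
            state=int(row["state"]) - 1,
            n_frames=int(row["n_frames"]), matrix=matrix,
            shrinkage=row.get("shrinkage")))
    return entries


def stage_netload(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    cohort = _load_prepped(out_dir)
    profiles = []
    if config.netload_source == "model":
        # summarize the fitted model's state covariances (as Fisher-z
        # correlations, matching the subject-level matrices' scale)
        model = hmm_mod.GaussianHMMModel.from_json(
            _require(out_dir / "model.json", "select"))
        for state in range(model.k):
            cov = model.covariances[state]
            d = np.sqrt(np.diag(cov))
            z = prep_mod.fisher_z(cov / np.outer(d, d))
            np.fill_diagonal(z, 0.0)
            profiles.append(nl.state_network_load(
                z, cohort.atlas, state,
                neutral_band=config.neutral_band))
        table = nl.network_load_table(profiles)
        table.to_csv(out_dir / "network_load.tsv", sep="\t", index=False)
        return table
    entries = _reload_entries(out_dir, cohort)
    n_states = max(e.state for e in entries) + 1
    for state in range(n_states):
        mats = [e.matrix for e in entries if e.state == state and e.present]
        if not mats:
            logger.warning("state %d: no available matrices for network "
                           "load", state + 1)
            continue
        mean_fc = np.mean(np.stack(mats), axis=0)
        profiles.append(nl.state_network_load(
            mean_fc, cohort.atlas, state,
            neutral_band=config.neutral_band))
    table = nl.network_load_table(profiles)
    table.to_csv(out_dir / "network_load.tsv", sep="\t", index=False)
    return table


def _metric_arrays(df: pd.DataFrame, value: str, k: int
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for state in range(1, k + 1):
        sub = df[df["state"] == state].dropna(subset=[value])
        out[f"S{state}"] = (
            sub.loc[sub["group"] == "control", value].to_numpy(float),
            sub.loc[sub["group"] == "patient", value].to_numpy(float))
    return out


def stage_stats(config: RunConfig, out_dir: Path) -> dict[str, pd.DataFrame]:
    cohort = _load_prepped(out_dir)
    fo = pd.read_csv(_require(out_dir / "fo.tsv", "metrics"), sep="\t",
                     dtype={"subject_id": str})
    mdt = pd.read_csv(out_dir / "mdt.tsv", sep="\t",
                      dtype={"subject_id": str})
    sw = pd.read_csv(out_dir / "switching.tsv", sep="\t",
                     dtype={"subject_id": str})
    k = int(fo["state"].max())
    parts = [stats_mod.compare_metric_family(
                 _metric_arrays(fo, "fo", k), family="fo"),
             stats_mod.compare_metric_family(
                 _metric_arrays(mdt, "mdt_tr", k), family="mdt")]
    sw_groups = (sw.loc[sw["group"] == "control",
                        "switching_rate"].dropna().to_numpy(float),
                 sw.loc[sw["group"] == "patient",
                        "switching_rate"].dropna().to_numpy(float))
    sw_res = stats_mod.compare_metric(*sw_groups, identifier="switching",
                                      family="switching")
    sw_df = pd.DataFrame([vars(sw_res)])
    sw_df["q"] = sw_df["p"]  # family of one
    parts.append(sw_df)
    stats_metrics = pd.concat(parts, ignore_index=True)

    tpms_by_group: dict[str, list] = {"control": [], "patient": []}
    for s in cohort.subjects:
        tpm = io_mod.read_matrix(
            _require(out_dir / f"tpm_subject_{s.subject_id}.tsv",
                     "metrics"))
        empty = tpm.sum(axis=1) == 0
        tpms_by_group[s.group].append((tpm, empty))
    stats_transitions = stats_mod.compare_tpm(tpms_by_group)

    entries = _reload_entries(out_dir, cohort)
    groups = {s.subject_id: s.group for s in cohort.subjects}
    stats_edges = stats_mod.edgewise_welch(entries, groups, n_states=k)

    out = {"stats_metrics": stats_metrics,
           "stats_transitions": stats_transitions,
           "stats_edges": stats_edges}
    for name, df in out.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return out


def stage_correlate(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    cohort = _load_prepped(out_dir)
    fo = pd.read_csv(_require(out_dir / "fo.tsv", "metrics"), sep="\t",
                     dtype={"subject_id": str})
    mdt = pd.read_csv(out_dir / "mdt.tsv", sep="\t",
                      dtype={"subject_id": str})
    sw = pd.read_csv(out_dir / "switching.tsv", sep="\t",
                     dtype={"subject_id": str})
    patients = [s.subject_id for s in cohort.subjects
                if s.group == "patient"]
    metrics = pd.DataFrame(index=pd.Index(patients, name="subject_id"))
    for state, grp in fo.groupby("state"):
        metrics[f"fo_S{state}"] = grp.set_index("subject_id")["fo"]
    for state, grp in mdt.groupby("state"):
        metrics[f"mdt_S{state}"] = grp.set_index("subject_id")["mdt_tr"]
    metrics["switching_rate"] = sw.set_index("subject_id")[
        "switching_rate"]
    # total off-diagonal transition count from the Viterbi path
    vit = pd.read_csv(_require(out_dir / "viterbi.tsv", "decode"),
                      sep="\t", dtype={"subject_id": str})
    seg_map = {s.subject_id: s.segments for s in cohort.subjects}
    k = int(fo["state"].max())
    changes = {}
    for sid in patients:
        path = vit[vit["subject_id"] == sid].sort_values(
            "t")["state"].to_numpy(int) - 1
        counts = dyn.transition_counts(path, seg_map[sid], k)
        changes[sid] = float(counts.sum() - np.trace(counts))
    metrics["n_state_changes"] = pd.Series(changes)
    corr = stats_mod.clinical_correlations(metrics,
                                           cohort.clinical.loc[patients])
    corr.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    return corr


def run(cohort: CohortDataset, config: RunConfig, out_dir: str | Path,
        stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order.

    ``cohort`` may be None when every requested stage can start from
    artifacts already in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    requested = list(stages) if stages else list(STAGES)
    bad = set(requested) - set(STAGES)
    if bad:
        raise ValidationError(f"unknown stage(s): {sorted(bad)}")
    ordered = [s for s in STAGES if s in requested]
    timings = {}
    results: dict = {}
    for stage in ordered:
        t0 = time.perf_counter()
        if stage == "prep":
            if cohort is None:
                raise DependencyError("stage 'prep' needs an input cohort")
            results["prep"] = stage_prep(cohort, config, out_dir)
        elif stage == "select":
            results["select"] = stage_select(config, out_dir)
        elif stage == "decode":
            results["decode"] = stage_decode(config, out_dir)
        elif stage == "metrics":
            results["metrics"] = stage_metrics(config, out_dir)
        elif stage == "connectivity":
            results["connectivity"] = stage_connectivity(config, out_dir)
        elif stage == "netload":
            results["netload"] = stage_netload(config, out_dir)
        elif stage == "stats":
            results["stats"] = stage_stats(config, out_dir)
        elif stage == "correlate":
            results["correlate"] = stage_correlate(config, out_dir)
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])
    manifest = {"config": asdict(config),
                "config_hash": config.config_hash(),
                "seed": config.seed, "stages": ordered,
                "timings_seconds": timings}
    io_mod.write_results({}, out_dir, run_info=manifest)
    return results
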