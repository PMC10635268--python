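"""End-to-end pipeline: simulate -> preprocess -> align -> detect -> bias -> ISC.

A run is driven by one flat config document (YAML or a dict) with one
section per stage; unknown keys are rejected so typos in resampling
counts cannot silently change an analysis.  Every stage writes plain
tables (CSV/TSV) plus a JSON manifest recording the config snapshot,
per-stage seeds, software version, output digests, and the analysis
switches in effect, which together determine a rerun.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from ._version import __version__
from .behavior import fisher_aggregate, isc_behavior_correlations, loo_isc
from .bias import fdr_bh, group_difference_test, map_trs_to_bins, session_delta_test
from .io import read_study
from .labels import LabelTrack, median_split_track, read_feature_track
from .preprocess import (
    VoxelSeries,
    clean_series,
    drop_initial_trs,
    extract_global_component,
    selective_component,
)
from .simulate import SimConfig, simulate_study
from .srm import fit_srm_k1, project_subjects
from .sync import find_sync_trs

log = logging.getLogger("cuesync")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "cuesync_run",
    "inputs": {"study_dir": None},
    "simulate": {},  # SimConfig field overrides
    "preprocess": {"n_drop": 10, "highpass_period": 140.0},
    "srm": {"tol": 1e-8, "max_iter": 100, "per_session": True},
    "sync": {
        "n_boot": 5000,
        "n_phase": 5000,
        "ci_level": 95.0,
        "null_percentile": 95.0,
        "detect_negative": False,
    },
    # control_tracks: {name: path} of per-bin scalar feature tracks
    # (e.g. loudness, brightness); each is median-split into a binary
    # track and run through the same bias tests.
    "bias": {"n_perm": 5000, "lag_lo": 5, "lag_hi": 10, "fdr_q": 0.05, "control_tracks": {}},
    "behavior": {
        "ofc_rois": None,  # default: the study's designated (truth) ROI set
        "group": "HUD",
        "measures": [
            "scene_induced_craving_max",
            "pre_movie_craving",
            "movie_induced_craving",
            "hcq_total",
        ],
        "fdr_q": 0.05,
    },
    "save_series": True,
}

ANALYSIS_SWITCHES = {
    "stage_order": "drop -> clean -> global -> selective -> srm -> sync -> bias -> isc",
    "highpass": "cosine drift basis projected jointly with confounds",
    "srm_fit": "per group and session, deterministic PCA initialization",
    "detection": "one-sided (positive median deflections) unless detect_negative",
    "ci_type": "percentile bootstrap",
    "null_placement": "uniform without replacement over valid TRs",
    "undefined_bias": "ROIs with empty T* excluded from FDR",
    "tr_offset": "+n_drop seconds restored before the hemodynamic lag window",
}


@dataclass
class RunManifest:
    """Everything needed to reproduce a run."""

    config: dict
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    switches: dict = field(default_factory=lambda: dict(ANALYSIS_SWITCHES))

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _merge_config(user: dict | None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if user is None:
        return config
    for key, value in user.items():
        if key not in config:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(config[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            if key != "simulate":
                for sub in value:
                    if sub not in config[key]:
                        raise KeyError(f"unknown config key: {key}.{sub}")
            config[key].update(value)
        else:
            config[key] = value
    valid_sim = {f.name for f in dataclasses.fields(SimConfig)}
    for sub in config["simulate"]:
        if sub not in valid_sim:
            raise KeyError(f"unknown config key: simulate.{sub}")
    return config


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = path_or_dict
    return _merge_config(user)


def _child_seed(seed: int, *names) -> int:
    return int(substream(seed, *names).integers(2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(paths: dict) -> list[str]:
    """Check declared inputs against their schemas; return violations."""
    violations: list[str] = []
    label_path = paths.get("label_track")
    if label_path is not None:
        try:
            LabelTrack.from_tsv(label_path)
        except Exception as exc:  # schema violation, not a crash
            violations.append(f"label_track {label_path}: {exc}")
    behavior_path = paths.get("behavior")
    if behavior_path is not None:
        required = {"subject_id", "group", "session"}
        try:
            df = pd.read_csv(behavior_path)
            missing = required - set(df.columns)
            if missing:
                violations.append(f"behavior {behavior_path}: missing columns {sorted(missing)}")
        except Exception as exc:
            violations.append(f"behavior {behavior_path}: {exc}")
    study_dir = paths.get("study_dir")
    if study_dir is not None:
        study_dir = Path(study_dir)
        sidecar_path = study_dir / "sidecar.json"
        if not sidecar_path.exists():
            violations.append(f"study_dir {study_dir}: missing sidecar.json")
        else:
            sidecar = json.loads(sidecar_path.read_text())
            for name, shape in sidecar.get("shapes", {}).items():
                arr_path = study_dir / "arrays" / f"{name}.npy"
                if not arr_path.exists():
                    violations.append(f"study_dir: missing array {name}.npy")
                    continue
                arr = np.load(arr_path, mmap_mode="r")
                if list(arr.shape) != list(shape):
                    violations.append(
                        f"study_dir: array {name} shape {list(arr.shape)} != sidecar {shape}"
                    )
    return violations


def process_group_session(
    roi_arrays: dict[int, np.ndarray],
    confounds: np.ndarray,
    n_drop: int = 10,
    highpass_period: float = 140.0,
    tr_seconds: float = 1.0,
    srm_tol: float = 1e-8,
    srm_max_iter: int = 100,
    group: str = "",
    extra_voxels: np.ndarray | None = None,
) -> dict[int, object]:
    """drop -> clean -> global -> selective -> SRM for one group/session.

    ``roi_arrays[r]`` is a (subject, voxel, TR) array; returns one
    z-scored :class:`~cuesync.srm.SubjectSeriesSet` per ROI.
    ``extra_voxels`` (subject, voxel, TR), when given, are gray-matter
    voxels outside the analyzed ROIs: they are cleaned the same way
    and enter the per-subject global average, but no further analysis.
    """
    n_subj = confounds.shape[0]
    roi_ids = list(roi_arrays)
    # All ROIs of a subject share one confound/drift design, so their
    # voxels are cleaned in a single stacked projection.
    splits = np.cumsum([roi_arrays[r].shape[1] for r in roi_ids])[:-1]
    cleaned: list[dict[int, VoxelSeries]] = []
    for i in range(n_subj):
        stacked = np.vstack([roi_arrays[r][i] for r in roi_ids])
        n_roi_vox = stacked.shape[0]
        if extra_voxels is not None and extra_voxels.shape[1] > 0:
            stacked = np.vstack([stacked, extra_voxels[i]])
        vs = VoxelSeries(values=stacked, tr_seconds=tr_seconds, subject_id=f"{group}{i:03d}")
        vs = drop_initial_trs(vs, n_drop)
        vs = clean_series(
            vs, confounds=confounds[i, n_drop:, :], highpass_period=highpass_period
        )
        gcomp = extract_global_component(vs)
        vs = selective_component(vs, gcomp)
        per_roi = {
            r: VoxelSeries(
                values=block,
                tr_seconds=tr_seconds,
                subject_id=f"{group}{i:03d}",
                roi_id=r,
                tr_offset=vs.tr_offset,
            )
            for r, block in zip(roi_ids, np.split(vs.values[:n_roi_vox], splits))
        }
        cleaned.append(per_roi)
    out: dict[int, object] = {}
    for r in roi_arrays:
        mats = [cleaned[i][r].values for i in range(n_subj)]
        fit = fit_srm_k1(mats, tol=srm_tol, max_iter=srm_max_iter)
        out[r] = project_subjects(
            fit, mats, subject_ids=[f"{group}{i:03d}" for i in range(n_subj)], roi_id=r
        )
    return out


def _preprocess_and_align(study, config):
    """drop -> clean -> global -> selective -> SRM, per group/session/ROI."""
    pre = config["preprocess"]
    series_sets: dict[tuple[str, str, int], object] = {}
    for g in study.voxel_data:
        for s in study.voxel_data[g]:
            per_roi = process_group_session(
                study.voxel_data[g][s],
                study.confounds[g][s],
                n_drop=int(pre["n_drop"]),
                highpass_period=float(pre["highpass_period"]),
                tr_seconds=study.config.tr_seconds,
                srm_tol=float(config["srm"]["tol"]),
                srm_max_iter=int(config["srm"]["max_iter"]),
                group=g,
                extra_voxels=(study.unassigned_voxels or {}).get(g, {}).get(s),
            )
            for r, sset in per_roi.items():
                series_sets[(g, s, r)] = sset
    return series_sets


def _detect_all(series_sets, config, seed):
    sync_cfg = config["sync"]
    results = {}
    seeds = {}
    for key, sset in series_sets.items():
        child = _child_seed(seed, "sync", *key)
        seeds["sync/" + "/".join(map(str, key))] = child
        results[key] = find_sync_trs(
            sset,
            n_boot=int(sync_cfg["n_boot"]),
            n_phase=int(sync_cfg["n_phase"]),
            ci_level=float(sync_cfg["ci_level"]),
            null_percentile=float(sync_cfg["null_percentile"]),
            seed=child,
            detect_negative=bool(sync_cfg["detect_negative"]),
        )
    return results, seeds


def _bias_tables(sync_results, track, config, seed, n_analyzed, n_drop, groups, sessions):
    bias_cfg = config["bias"]
    valid_trs = np.arange(n_analyzed)
    rois = sorted({key[2] for key in sync_results})
    s1, s2 = sessions
    ga, gb = groups
    rows = []
    for r in rois:
        t_sets = {
            (g, s): sync_results[(g, s, r)].significant_trs for g in groups for s in sessions
        }
        base = group_difference_test(
            t_sets[(ga, s1)],
            t_sets[(gb, s1)],
            track,
            valid_trs,
            n_perm=int(bias_cfg["n_perm"]),
            seed=_child_seed(seed, "bias-baseline"),
            tr_offset_seconds=n_drop,
            lag_lo=int(bias_cfg["lag_lo"]),
            lag_hi=int(bias_cfg["lag_hi"]),
            roi_id=r,
        )
        delta = session_delta_test(
            t_sets,
            track,
            valid_trs,
            n_perm=int(bias_cfg["n_perm"]),
            seed=_child_seed(seed, "bias-delta"),
            tr_offset_seconds=n_drop,
            lag_lo=int(bias_cfg["lag_lo"]),
            lag_hi=int(bias_cfg["lag_hi"]),
            roi_id=r,
            groups=groups,
            sessions=sessions,
        )
        rows.append(
            {
                "roi_id": r,
                f"bias_{ga}_base": delta.bias[f"{ga}_{s1}"],
                f"bias_{gb}_base": delta.bias[f"{gb}_{s1}"],
                f"bias_{ga}_follow": delta.bias[f"{ga}_{s2}"],
                f"bias_{gb}_follow": delta.bias[f"{gb}_{s2}"],
                "stat_baseline": base.statistic,
                "p_baseline": base.p_value,
                "stat_delta": delta.statistic,
                "p_delta": delta.p_value,
                **{f"n_sync_{g}_{s}": len(t_sets[(g, s)]) for g in groups for s in sessions},
            }
        )
    table = pd.DataFrame(rows)
    for family in ("baseline", "delta"):
        q, rej = fdr_bh(table[f"p_{family}"].to_numpy(), q=float(bias_cfg["fdr_q"]))
        table[f"q_{family}"] = q
        table[f"sig_{family}"] = rej
    return table


def _isc_tables(series_sets, study, config, groups, sessions):
    beh_cfg = config["behavior"]
    ofc_rois = beh_cfg["ofc_rois"]
    if ofc_rois is None:
        ofc_rois = list(
            study.truth.get("ofc_rois") or study.truth.get("drug_locked_rois", [])
        )
    ofc_rois = [int(r) for r in ofc_rois]
    if not ofc_rois:
        raise ValueError("no OFC ROI set configured and none recorded in the study truth")
    rows = []
    for g in groups:
        for s in sessions:
            per_roi = {r: loo_isc(series_sets[(g, s, r)]) for r in ofc_rois}
            ids = series_sets[(g, s, ofc_rois[0])].subject_ids
            for i, sid in enumerate(ids):
                r_values = np.clip([per_roi[r][i] for r in ofc_rois], -0.999999, 0.999999)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": g,
                        "session": s,
                        "isc": fisher_aggregate(r_values),
                        **{f"isc_roi{r}": per_roi[r][i] for r in ofc_rois},
                    }
                )
    isc_table = pd.DataFrame(rows)
    target_group = beh_cfg["group"]
    behavior = study.behavior[study.behavior["group"] == target_group]
    isc_sub = isc_table[isc_table["group"] == target_group][["subject_id", "session", "isc"]]
    measures = [m for m in beh_cfg["measures"] if behavior[m].notna().any()]
    corr = isc_behavior_correlations(
        isc_sub, behavior, measures, sessions=sessions, q=float(beh_cfg["fdr_q"])
    )
    return isc_table, corr


def _carpet_table(sync_results, track, n_analyzed, n_drop, config, group, session):
    bias_cfg = config["bias"]
    lag_lo, lag_hi = int(bias_cfg["lag_lo"]), int(bias_cfg["lag_hi"])
    rois = sorted({key[2] for key in sync_results if key[0] == group and key[1] == session})
    frac = np.full(n_analyzed, np.nan)
    for t in range(n_analyzed):
        bins = map_trs_to_bins([t], track.n_bins, n_drop, lag_lo, lag_hi)
        if bins.size:
            frac[t] = track.labels[bins].mean()
    data = {"tr": np.arange(n_analyzed), "mapped_drug_fraction": frac}
    for r in rois:
        sig = np.zeros(n_analyzed, dtype=int)
        sig[sync_results[(group, session, r)].significant_trs] = 1
        data[f"roi{r}"] = sig
    return pd.DataFrame(data)


def run_pipeline(config_path_or_dict, output_dir: str | Path | None = None) -> Path:
    """Run the full analysis; returns the result directory.

    Any stage failure aborts with the stage name in the exception
    message.
    """
    config = load_config(config_path_or_dict)
    seed = int(config["seed"])
    out = Path(output_dir if output_dir is not None else config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=copy.deepcopy(config))
    manifest.seeds["top"] = seed

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("inputs")
    try:
        study_dir = config["inputs"]["study_dir"]
        if study_dir is not None:
            violations = validate_inputs({"study_dir": study_dir})
            if violations:
                raise ValueError(f"input validation failed: {violations}")
            study = read_study(study_dir)
        else:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", _child_seed(seed, "simulate"))
            study = simulate_study(SimConfig(**sim_kwargs))
            manifest.seeds["simulate"] = study.config.seed
        groups = tuple(study.voxel_data)
        sessions = tuple(next(iter(study.voxel_data.values())))
        n_drop = int(config["preprocess"]["n_drop"])
        n_analyzed = study.config.n_trs - n_drop
        track = study.label_track

        current = stage("preprocess+align")
        series_sets = _preprocess_and_align(study, config)
        if config["save_series"]:
            series_dir = out / "series"
            series_dir.mkdir(exist_ok=True)
            for (g, s, r), sset in series_sets.items():
                df = pd.DataFrame(sset.values.T, columns=sset.subject_ids)
                df.to_csv(series_dir / f"{g}_{s}_roi{r}.tsv", sep="\t", index=False)

        current = stage("sync-detection")
        sync_results, sync_seeds = _detect_all(series_sets, config, seed)
        manifest.seeds.update(sync_seeds)
        sync_json = {
            "/".join(map(str, key)): res.to_dict() for key, res in sync_results.items()
        }
        (out / "sync_results.json").write_text(json.dumps(sync_json, indent=2))
        for g in groups:
            for s in sessions:
                carpet = _carpet_table(sync_results, track, n_analyzed, n_drop, config, g, s)
                carpet.to_csv(out / f"carpet_{g}_{s}.tsv", sep="\t", index=False)

        current = stage("bias")
        bias_table = _bias_tables(
            sync_results, track, config, seed, n_analyzed, n_drop, groups, sessions
        )
        bias_table.to_csv(out / "bias_results.csv", index=False)
        for name, path in dict(config["bias"]["control_tracks"]).items():
            control = median_split_track(read_feature_track(path), f"{name}_high")
            control_table = _bias_tables(
                sync_results, control, config, seed, n_analyzed, n_drop, groups, sessions
            )
            control_table.to_csv(out / f"bias_results_{name}.csv", index=False)

        current = stage("isc-behavior")
        isc_table, corr_table = _isc_tables(series_sets, study, config, groups, sessions)
        isc_table.to_csv(out / "isc_scores.csv", index=False)
        corr_table.to_csv(out / "isc_behavior_correlations.csv", index=False)

        current = stage("report")
        _write_report(out, bias_table, corr_table, groups)
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest.digests[str(f.relative_to(out))] = _sha256(f)
        manifest.write(out / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    return out


def _write_report(out: Path, bias_table, corr_table, groups) -> None:
    lines = ["cuesync run report", "=" * 40, ""]
    n_base = int(bias_table["sig_baseline"].sum())
    n_delta = int(bias_table["sig_delta"].sum())
    both = bias_table[bias_table["sig_baseline"] & bias_table["sig_delta"]]["roi_id"].tolist()
    lines.append(f"ROIs with significant baseline group bias difference: {n_base}")
    lines.append(f"ROIs with significant group difference in session delta: {n_delta}")
    lines.append(f"ROIs showing both effects: {both}")
    lines.append("")
    lines.append("ISC-behavior correlations:")
    for _, row in corr_table.iterrows():
        flag = "*" if row["significant"] else " "
        lines.append(
            f"  {flag} {row['measure']} ({row['session_or_delta']}): "
            f"r={row['r']:.3f}, p={row['p']:.4f}, q={row['q']:.4f}, n={row['n']}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
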