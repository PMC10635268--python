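"""On-disk study container: binary arrays + JSON sidecar + flat tables.

Layout written by :func:`write_study` / read back by :func:`read_study`::

    study_dir/
      sidecar.json                 # shapes, indexing, config, seed
      label_track.tsv              # bin_start_second, label
      behavior.csv
      truth.json
      arrays/{group}_{session}_roi{r}.npy   # (subject, voxel, TR)
      confounds/{group}_{session}.npy       # (subject, TR, k)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import LabelTrack
from .simulate import SimConfig, SyntheticStudy

CONFOUND_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "csf")


def write_study(study: SyntheticStudy, path: str | Path) -> Path:
    path = Path(path)
    (path / "arrays").mkdir(parents=True, exist_ok=True)
    (path / "confounds").mkdir(exist_ok=True)
    study.label_track.to_tsv(path / "label_track.tsv")
    study.behavior.to_csv(path / "behavior.csv", index=False)
    shapes: dict[str, list[int]] = {}
    for g in study.voxel_data:
        for s in study.voxel_data[g]:
            np.save(path / "confounds" / f"{g}_{s}.npy", study.confounds[g][s])
            for r, arr in study.voxel_data[g][s].items():
                name = f"{g}_{s}_roi{r}"
                np.save(path / "arrays" / f"{name}.npy", arr)
                shapes[name] = list(arr.shape)
            extra = (study.unassigned_voxels or {}).get(g, {}).get(s)
            if extra is not None and extra.shape[1] > 0:
                name = f"{g}_{s}_unassigned"
                np.save(path / "arrays" / f"{name}.npy", extra)
                shapes[name] = list(extra.shape)
    sidecar = {
        "groups": list(study.voxel_data),
        "sessions": list(next(iter(study.voxel_data.values()))),
        "n_rois": study.config.n_rois,
        "shapes": shapes,
        "seed": study.config.seed,
        "config": dataclasses.asdict(study.config),
        "confound_columns": list(CONFOUND_COLUMNS[: study.config.n_confounds]),
    }
    (path / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    (path / "truth.json").write_text(json.dumps(study.truth, indent=2))
    return path


def read_study(path: str | Path) -> SyntheticStudy:
    path = Path(path)
    sidecar = json.loads((path / "sidecar.json").read_text())
    cfg_dict = sidecar["config"]
    for key in (
        "n_subjects_per_group",
        "drug_locked_rois",
        "ofc_rois",
        "coupling_range",
        "scene_gain_range",
    ):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg_dict["drug_amplitude"] = tuple(tuple(r) for r in cfg_dict["drug_amplitude"])
    cfg_dict["nondrug_amplitude"] = tuple(tuple(r) for r in cfg_dict["nondrug_amplitude"])
    config = SimConfig(**cfg_dict)
    track = LabelTrack.from_tsv(path / "label_track.tsv")
    behavior = pd.read_csv(path / "behavior.csv")
    truth = json.loads((path / "truth.json").read_text())
    voxel_data: dict = {}
    confounds: dict = {}
    unassigned: dict = {}
    for g in sidecar["groups"]:
        voxel_data[g] = {}
        confounds[g] = {}
        unassigned[g] = {}
        for s in sidecar["sessions"]:
            confounds[g][s] = np.load(path / "confounds" / f"{g}_{s}.npy")
            voxel_data[g][s] = {
                r: np.load(path / "arrays" / f"{g}_{s}_roi{r}.npy")
                for r in range(sidecar["n_rois"])
            }
            extra_path = path / "arrays" / f"{g}_{s}_unassigned.npy"
            if extra_path.exists():
                unassigned[g][s] = np.load(extra_path)
    return SyntheticStudy(
        config=config,
        voxel_data=voxel_data,
        label_track=track,
        confounds=confounds,
        behavior=behavior,
        truth=truth,
        unassigned_voxels=unassigned,
    )
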