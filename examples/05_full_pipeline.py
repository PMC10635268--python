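"""End-to-end reproducible run from one config.

Simulates a small study, runs preprocessing, alignment, detection,
bias tests, and ISC-behavior correlations, then prints the report.
Equivalent shell command:  cuesync run config.yaml
"""

from pathlib import Path

from cuesync import run_pipeline

config = {
    "seed": 17,
    "simulate": {
        "n_subjects_per_group": (10, 10),
        "n_rois": 8,
        "voxels_per_roi": 20,
        "n_unassigned_voxels": 100,
        "n_trs": 310,
        "drug_locked_rois": (0, 1),
        "ofc_rois": (2, 3),
    },
    "sync": {"n_boot": 500, "n_phase": 500},
    "bias": {"n_perm": 500},
    "save_series": False,
}

out = run_pipeline(config, output_dir="scratch/demo_run")
print((Path(out) / "report.txt").read_text())
print(f"tables written to {out}/")
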