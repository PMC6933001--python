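#!/usr/bin/env python
"""Voxel-based lesion-symptom mapping of the three praxis tasks.

For each task, fits the per-voxel linear model (score ~ lesion status +
age + handedness + total lesion volume + orientation) over voxels
lesioned in >= 10 patients, applies Benjamini-Hochberg FDR at q = 0.05,
and extracts significant clusters with peak template-space coordinates.
Cluster tables go to results/analysis/, statistical maps to scratch/.
"""

from pathlib import Path

import pandas as pd

from ctvlsm.pipeline import load_volumes
from ctvlsm.vlsm import run_vlsm

ROOT = Path(__file__).resolve().parent.parent
DELIN = ROOT / "scratch" / "analysis" / "delineation"
SCRATCH = ROOT / "scratch" / "analysis" / "vlsm"
RESULTS = ROOT / "results" / "analysis"

TASKS = ("gesture_production", "gesture_recognition", "gesture_imitation")


def main() -> None:
    lesions = load_volumes(DELIN / "lesions")
    table = pd.read_csv(RESULTS / "behavior_with_volumes.csv")
    SCRATCH.mkdir(parents=True, exist_ok=True)

    all_clusters = []
    for task in TASKS:
        res = run_vlsm(lesions, table, task, min_count=10, q=0.05)
        tdir = SCRATCH / task
        tdir.mkdir(exist_ok=True)
        for name in ("beta", "t", "p", "q"):
            getattr(res, name).save(tdir / f"{name}.nii.gz")
        res.sig_mask.save(tdir / "significant.nii.gz")
        clusters = res.clusters.copy()
        clusters.insert(0, "task", task)
        all_clusters.append(clusters)
        print(f"{task}: {res.metadata['n_tested']} voxels tested, "
              f"{res.metadata['n_significant']} significant, "
              f"{len(res.clusters)} cluster(s)")
        for _, row in res.clusters.iterrows():
            print(f"    cluster {int(row.cluster_id)}: {row.volume_mm3:.0f} mm^3, "
                  f"peak t={row.peak_t:.2f} at "
                  f"({row.x_mm:.0f}, {row.y_mm:.0f}, {row.z_mm:.0f}) mm")

    nonempty = [c for c in all_clusters if len(c)]
    out = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=all_clusters[0].columns)
    )
    out.to_csv(RESULTS / "vlsm_clusters.csv", index=False)
    print(f"cluster table -> {RESULTS / 'vlsm_clusters.csv'}")


if __name__ == "__main__":
    main()
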