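"""Reusable simulation experiments that characterize the pipeline.

Each experiment generates its own synthetic data from a seed, runs the
relevant pipeline stage, and returns summary measurements.  They back
both the validation test-suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .delineate import ControlSet, tscore_map
from .pipeline import DelineationConfig, PreprocessConfig, delineate_cohort
from .preprocess import AffineTransform, register_affine, resample, smooth_gaussian
from .synthetic import SimulationConfig, generate_cohort, generate_control_volume
from .vlsm import permutation_null_fdp, run_vlsm
from .volume import dice

__all__ = [
    "null_calibration",
    "lesion_recovery",
    "vlsm_recovery",
    "permutation_fdp_experiment",
    "monotone_power",
    "registration_recovery",
]


def null_calibration(
    seed: int = 0,
    alphas=(0.05, 0.001),
    n_replicates: int = 16,
    k: int = 30,
    cfg: SimulationConfig | None = None,
    fwhm_mm: float = 4.0,
) -> dict:
    """Per-voxel rejection rate of the abnormality map under the null.

    Each replicate draws an independent control set of size ``k`` and
    one lesion-free "patient" from the same law, smooths all volumes
    identically, and measures the fraction of within-brain voxels whose
    one-tailed p falls below each alpha.  Smoothing is linear, so the
    per-voxel statistic is exactly Student-t under the Gaussian noise
    law and the rate should match alpha.

    Returns ``{alpha: {"rates": per-replicate array, "mean": .., "se": ..}}``.
    """
    cfg = cfg or SimulationConfig(n_controls=k)
    brain = cfg.brain_mask()
    results = {a: [] for a in alphas}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        controls = [
            smooth_gaussian(generate_control_volume(cfg, rng), fwhm_mm) for _ in range(k)
        ]
        case = smooth_gaussian(generate_control_volume(cfg, rng), fwhm_mm)
        cs = ControlSet.from_volumes(controls)
        tm = tscore_map(case, cs)
        valid = (tm.valid.data > 0) & brain
        t = tm.t.data[valid]
        from scipy import stats

        for a in alphas:
            crit = stats.t.isf(a, tm.df)
            results[a].append(float((t < -crit).mean()))
    out = {}
    for a in alphas:
        rates = np.asarray(results[a])
        out[a] = {
            "rates": rates,
            "mean": float(rates.mean()),
            "se": float(rates.std(ddof=1) / np.sqrt(len(rates))),
        }
    return out


def lesion_recovery(
    seed: int = 0,
    n_patients: int = 20,
    cfg: SimulationConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    delin_cfg: DelineationConfig | None = None,
) -> dict:
    """Dice between delineated and true lesions over a synthetic cohort."""
    cfg = cfg or SimulationConfig()
    cfg = replace(cfg, n_patients=n_patients, seed=seed)
    cohort = generate_cohort(cfg)
    res = delineate_cohort(cohort.controls, cohort.patients, pre_cfg, delin_cfg)
    dices = np.array(
        [dice(est, true) for est, true in zip(res["lesions"], cohort.truth.lesions)]
    )
    return {
        "dice": dices,
        "median_dice": float(np.median(dices)),
        "lesion_volumes_mm3": res["lesion_volumes_mm3"],
        "cohort": cohort,
        "delineation": res,
    }


def _dilated_critical_mask(cohort, n_voxels: int = 3) -> np.ndarray:
    from scipy import ndimage

    crit = cohort.truth.critical_region.data > 0
    return ndimage.binary_dilation(crit, iterations=n_voxels)


def vlsm_recovery(
    seed: int = 0,
    n_patients: int = 100,
    tasks=("gesture_production", "gesture_recognition", "gesture_imitation"),
    cfg: SimulationConfig | None = None,
    min_count: int = 10,
    q: float = 0.05,
    cohort=None,
    delineation=None,
) -> dict:
    """End-to-end VLSM on a synthetic cohort, scored against ground truth.

    For each task, reports the number of FDR-significant voxels and
    clusters and whether the top cluster's peak falls inside the
    3-voxel-dilated critical region.  A pre-built cohort/delineation
    pair may be supplied to share work across experiments.
    """
    if cohort is None:
        cfg = cfg or SimulationConfig()
        cfg = replace(cfg, n_patients=n_patients, seed=seed)
        cohort = generate_cohort(cfg)
    if delineation is None:
        delineation = delineate_cohort(cohort.controls, cohort.patients)
    lesions = delineation["lesions"]
    dil = _dilated_critical_mask(cohort)
    out = {"cohort": cohort, "delineation": delineation, "tasks": {}}
    for task in tasks:
        res = run_vlsm(lesions, cohort.table, task, min_count=min_count, q=q)
        peak_in = False
        if len(res.clusters):
            top = res.clusters.iloc[0]
            peak_vox = np.round(
                res.t.world_to_voxel([top["x_mm"], top["y_mm"], top["z_mm"]])
            ).astype(int)
            peak_in = bool(dil[tuple(peak_vox)])
        out["tasks"][task] = {
            "n_significant": res.metadata["n_significant"],
            "n_clusters": int(len(res.clusters)),
            "peak_in_critical_region": peak_in,
            "result": res,
        }
    return out


def permutation_fdp_experiment(
    seed: int = 0,
    n_perm: int = 200,
    task: str = "gesture_production",
    q: float = 0.05,
    cohort=None,
    delineation=None,
    n_patients: int = 100,
) -> dict:
    """Mean false-discovery proportion over seeded score permutations."""
    if cohort is None:
        cfg = replace(SimulationConfig(), n_patients=n_patients, seed=seed)
        cohort = generate_cohort(cfg)
    if delineation is None:
        delineation = delineate_cohort(cohort.controls, cohort.patients)
    fdps = permutation_null_fdp(
        delineation["lesions"], cohort.table, task, q=q, n_perm=n_perm, seed=seed + 1
    )
    return {
        "fdp": fdps,
        "mean_fdp": float(fdps.mean()),
        "se": float(fdps.std(ddof=1) / np.sqrt(len(fdps))) if len(fdps) > 1 else 0.0,
    }


def monotone_power(
    seed: int = 0,
    effect_scales=(0.25, 0.5, 1.0),
    n_patients: int = 100,
    task: str = "gesture_production",
    q: float = 0.05,
) -> dict:
    """Significant-voxel count as the behavioral effect size grows.

    Effects are ``scale x (task range)`` with the same seed throughout;
    the imaging data (and hence the delineated lesions) are identical
    across scales because behavioral noise uses an independent stream.
    """
    from .behavior import PRAXIS_TASKS, TASK_MAXIMA

    base = SimulationConfig()
    counts = []
    delineation = None
    for scale in effect_scales:
        effects = {t: scale * TASK_MAXIMA[t] for t in PRAXIS_TASKS}
        cfg = replace(base, n_patients=n_patients, seed=seed, effect_per_task=effects)
        cohort = generate_cohort(cfg)
        if delineation is None:
            delineation = delineate_cohort(cohort.controls, cohort.patients)
        res = run_vlsm(delineation["lesions"], cohort.table, task, q=q)
        counts.append(res.metadata["n_significant"])
    return {"effect_scales": list(effect_scales), "n_significant": counts}


def registration_recovery(
    seed: int = 0,
    n_draws: int = 10,
    max_translation_mm: float = 10.0,
    max_rotation_rad: float = 0.1,
    scale_range=(0.9, 1.1),
) -> dict:
    """Recover randomly drawn small affines on synthetic brains.

    A moving brain is generated, a known affine ``G`` (moving world ->
    template world) is drawn, the template is synthesized by resampling
    the moving image under ``G``, and ``register_affine`` must recover
    ``G``'s parameters.  Returns per-draw absolute errors.

    The phantom deliberately breaks the brain ellipsoid's symmetry
    (offset ventricles, textured parenchyma): for a perfectly
    symmetric ellipsoid the affine parameters are not identifiable
    (rotations can be absorbed by shear/scale), which is a property of
    the object, not of the optimizer.
    """
    # wider FOV than brain so translated templates are not cropped
    cfg = SimulationConfig(
        grid_shape=(56, 56, 56),
        brain_radii_mm=(15.0, 17.0, 15.0),
        noise_smoothness_mm=3.0,
        parenchyma_sd=4.0,
        csf_sd=2.0,
        ventricle_centers_mm=((-6.0, 3.0, 5.0), (4.0, -5.0, -1.0)),
        ventricle_radii_mm=(3.5, 6.0, 4.0),
        critical_center_mm=(-6.0, -3.0, 2.0),
        critical_radii_mm=(5.0, 5.0, 5.0),
    )
    rng = np.random.default_rng(seed)
    moving = generate_control_volume(cfg, rng)
    errs = {"translation_mm": [], "rotation_rad": [], "scale": []}
    for _ in range(n_draws):
        true = AffineTransform(
            translation=rng.uniform(-max_translation_mm, max_translation_mm, 3),
            rotation=rng.uniform(-max_rotation_rad, max_rotation_rad, 3),
            scale=rng.uniform(*scale_range, 3),
        )
        template = resample(moving, true, moving)
        est = register_affine(moving, template)
        errs["translation_mm"].append(np.abs(est.translation - true.translation).max())
        errs["rotation_rad"].append(np.abs(est.rotation - true.rotation).max())
        errs["scale"].append(np.abs(est.scale - true.scale).max())
    return {k: np.asarray(v) for k, v in errs.items()}
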