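"""Synthetic CT-like stroke cohorts with known ground truth.

The generator emulates the statistical structure the delineation and
lesion-symptom-mapping stages assume, at desk scale:

* control head volumes: an ellipsoidal brain at parenchyma-level
  intensity with interior ventricles at CSF level, zero background, and
  spatially smooth Gaussian intensity noise;
* patient volumes: the control law plus one ellipsoidal lesion whose
  intensity is shifted (negative shift = hypo-intense/ischemic,
  positive = hyper-intense/hemorrhagic);
* behavioral scores: a linear-in-overlap deficit model.  Each task
  score is ``clip(max - effect * overlap - age_slope * (age - mean_age)
  + noise, 0, max)`` rounded to the task's integer grid, where
  ``overlap`` is the fraction of a hidden critical region covered by
  the true lesion;
* demographics anchored to the study cohort the pipeline targets
  (age ~ Normal(72.39, 12.80) truncated to [27, 94]; 353/387
  right-handed).

Everything is reproducible from a single seed: independent child
streams drive volumes, demographics and behavioral noise, so changing
e.g. the behavioral effect sizes leaves the imaging data bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .behavior import PRAXIS_TASKS, TASK_MAXIMA
from .volume import Volume

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "ConfigurationError",
    "default_affine",
    "ellipsoid_mask",
    "generate_control_volume",
    "generate_patient_volume",
    "generate_behavior",
    "generate_cohort",
]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig cannot produce valid volumes."""


def default_affine(grid_shape, voxel_size_mm: float) -> np.ndarray:
    """RAS+ affine with isotropic spacing, world origin at the grid center."""
    shape = np.asarray(grid_shape, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size_mm
    affine[:3, 3] = -(shape - 1) / 2.0 * voxel_size_mm
    return affine


def _world_coords(shape, affine):
    """Per-axis world coordinate arrays broadcastable to ``shape``.

    Assumes an axis-aligned (diagonal) affine, which is all the
    generator ever builds.
    """
    coords = []
    for ax in range(3):
        idx = np.arange(shape[ax], dtype=float)
        w = affine[ax, ax] * idx + affine[ax, 3]
        sh = [1, 1, 1]
        sh[ax] = shape[ax]
        coords.append(w.reshape(sh))
    return coords


def ellipsoid_mask(shape, affine, center_mm, radii_mm) -> np.ndarray:
    """Boolean mask of the analytic ellipsoid (voxel centers inside)."""
    x, y, z = _world_coords(shape, affine)
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    d = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    return d <= 1.0


@lru_cache(maxsize=8)
def _smoothing_rms(sigma_vox: float, ndim: int = 3) -> float:
    # RMS of the normalized separable Gaussian kernel: smoothing unit white
    # noise divides its sd by this factor.
    if sigma_vox <= 0:
        return 1.0
    half = int(np.ceil(4 * sigma_vox)) + 2
    imp = np.zeros(2 * half + 1)
    imp[half] = 1.0
    k = ndimage.gaussian_filter1d(imp, sigma_vox)
    rms1d = float(np.sqrt((k**2).sum()))
    return rms1d**ndim


@dataclass
class SimulationConfig:
    # grid
    grid_shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 1.0
    # cohort sizes
    n_controls: int = 30
    n_patients: int = 20
    # tissue intensity law (arbitrary CT-like units)
    parenchyma_mean: float = 40.0
    parenchyma_sd: float = 2.0
    csf_mean: float = 10.0
    csf_sd: float = 2.0
    noise_smoothness_mm: float = 2.0  # sigma of the spatial noise correlation
    # anatomy (world mm; origin at grid center)
    brain_radii_mm: tuple = (20.0, 22.0, 20.0)
    ventricle_radii_mm: tuple = (4.0, 9.0, 5.0)
    ventricle_centers_mm: tuple = ((-7.0, 0.0, 4.0), (7.0, 0.0, 4.0))
    # lesion model
    lesion_intensity_shift: float = -25.0  # negative = ischemic (hypo-intense)
    lesion_radius_range_mm: tuple = (9.0, 15.0)
    # hidden critical region driving behavioral deficits
    critical_center_mm: tuple = (-8.0, -4.0, 2.0)
    critical_radii_mm: tuple = (7.0, 7.0, 7.0)
    # behavioral model: score points lost per unit overlap fraction
    effect_per_task: dict = field(
        default_factory=lambda: {
            "gesture_production": 6.0,
            "gesture_recognition": 3.0,
            "gesture_imitation": 6.0,
        }
    )
    picture_naming_effect: float = 7.0
    age_slope: float = 0.05  # score points lost per year above the cohort mean
    noise_sd_behavior: float = 1.0  # score points
    # demographics (distributional anchors of the target cohort)
    mean_age: float = 72.39
    age_sd: float = 12.80
    age_range: tuple = (27.0, 94.0)
    right_handed_frac: float = 353.0 / 387.0
    # orientation-in-time-and-space covariate: noisy monotone decreasing
    # function of relative lesion volume
    orientation_max: float = 14.0
    orientation_effect: float = 20.0  # points per unit lesion/brain volume ratio
    orientation_noise_sd: float = 1.5
    seed: int = 0

    # ---- derived geometry -------------------------------------------
    def affine(self) -> np.ndarray:
        return default_affine(self.grid_shape, self.voxel_size_mm)

    def brain_mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid_shape, self.affine(), (0.0, 0.0, 0.0), self.brain_radii_mm)

    def ventricle_mask(self) -> np.ndarray:
        aff = self.affine()
        mask = np.zeros(self.grid_shape, dtype=bool)
        for c in self.ventricle_centers_mm:
            mask |= ellipsoid_mask(self.grid_shape, aff, c, self.ventricle_radii_mm)
        return mask & self.brain_mask()

    def critical_mask(self) -> np.ndarray:
        return (
            ellipsoid_mask(self.grid_shape, self.affine(), self.critical_center_mm, self.critical_radii_mm)
            & self.brain_mask()
        )

    def validate(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or self.voxel_size_mm <= 0:
            raise ConfigurationError("grid shape and voxel size must be positive")
        if self.n_controls < 2:
            raise ConfigurationError("need at least 2 controls (case-control t needs df >= 1)")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi):
            raise ConfigurationError("lesion radii must be positive and ordered")
        if any(e < 0 for e in self.effect_per_task.values()):
            raise ConfigurationError("effect_per_task must be non-negative")
        # brain (plus a 1-voxel margin) must fit inside the field of view
        fov = np.asarray(self.grid_shape) * self.voxel_size_mm / 2.0
        if np.any(np.asarray(self.brain_radii_mm) + self.voxel_size_mm >= fov):
            raise ConfigurationError("grid too small to contain the brain ellipsoid")
        if not self.critical_mask().any():
            raise ConfigurationError("critical region lies outside the brain")


@dataclass
class GroundTruth:
    """True lesion masks, the critical region, and the generating law."""

    lesions: list  # list[Volume], binary, one per patient
    critical_region: Volume
    overlap: np.ndarray  # per-patient |lesion ∩ critical| / |critical|
    config: SimulationConfig

    def recompute_overlap(self) -> np.ndarray:
        crit = self.critical_region.data > 0
        denom = int(crit.sum())
        return np.array(
            [np.logical_and(l.data > 0, crit).sum() / denom for l in self.lesions]
        )


@dataclass
class Cohort:
    controls: list  # list[Volume]
    patients: list  # list[Volume]
    table: pd.DataFrame
    truth: GroundTruth


# ---- volume generation ----------------------------------------------


def _unit_noise(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(cfg.grid_shape)
    sigma_vox = cfg.noise_smoothness_mm / cfg.voxel_size_mm
    if sigma_vox <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma_vox)
    return smooth / _smoothing_rms(round(sigma_vox, 6))


def generate_control_volume(cfg: SimulationConfig, rng: np.random.Generator) -> Volume:
    """One control head volume: brain + ventricles + smooth noise.

    Background voxels are exactly zero; within-brain marginals are
    Gaussian with per-tissue mean/sd, spatially correlated on the
    ``noise_smoothness_mm`` scale.  Deterministic given the generator
    state.
    """
    cfg.validate()
    brain = cfg.brain_mask()
    vent = cfg.ventricle_mask()
    base = np.zeros(cfg.grid_shape, dtype=float)
    base[brain] = cfg.parenchyma_mean
    base[vent] = cfg.csf_mean
    sd_map = np.zeros(cfg.grid_shape, dtype=float)
    sd_map[brain] = cfg.parenchyma_sd
    sd_map[vent] = cfg.csf_sd
    noise = _unit_noise(cfg, rng)
    return Volume(base + noise * sd_map, cfg.affine(), space="template")


def generate_patient_volume(
    cfg: SimulationConfig, rng: np.random.Generator, max_retries: int = 20
) -> tuple[Volume, Volume]:
    """A control-law volume with one ellipsoidal lesion, plus its true mask.

    The lesion center is sampled uniformly among brain voxels deep
    enough that the whole ellipsoid stays inside the brain; radii are
    drawn per-axis from ``lesion_radius_range_mm``.  Intensities inside
    the lesion are shifted by ``lesion_intensity_shift``.
    """
    vol = generate_control_volume(cfg, rng)
    brain = cfg.brain_mask()
    dist = ndimage.distance_transform_edt(brain, sampling=cfg.voxel_size_mm)
    lo, hi = cfg.lesion_radius_range_mm
    for _ in range(max_retries):
        radii = rng.uniform(lo, hi, size=3)
        interior = dist >= radii.max() + cfg.voxel_size_mm
        candidates = np.flatnonzero(interior.ravel())
        if len(candidates) == 0:
            continue
        center_idx = np.unravel_index(candidates[rng.integers(len(candidates))], cfg.grid_shape)
        center_mm = vol.voxel_to_world(center_idx)
        # lesions damage tissue, not ventricular CSF
        lesion = (
            ellipsoid_mask(cfg.grid_shape, cfg.affine(), center_mm, radii)
            & brain
            & ~cfg.ventricle_mask()
        )
        if lesion.any():
            data = vol.data.copy()
            data[lesion] += cfg.lesion_intensity_shift
            return (
                Volume(data, cfg.affine(), space="template"),
                Volume(lesion.astype(np.uint8), cfg.affine(), space="template"),
            )
    raise ConfigurationError(
        "could not place a lesion inside the brain; lesion radii too large for the grid"
    )


# ---- behavioral generation ------------------------------------------


def generate_behavior(
    true_overlap: float, age: float, cfg: SimulationConfig, rng: np.random.Generator
) -> dict:
    """Per-task integer scores from the linear-in-overlap deficit model."""
    if not 0.0 <= true_overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    scores = {}
    for task in PRAXIS_TASKS:
        effect = cfg.effect_per_task.get(task, 0.0)
        top = TASK_MAXIMA[task]
        raw = (
            top
            - effect * true_overlap
            - cfg.age_slope * (age - cfg.mean_age)
            + (rng.normal(0.0, cfg.noise_sd_behavior) if cfg.noise_sd_behavior > 0 else 0.0)
        )
        scores[task] = float(np.clip(np.rint(np.clip(raw, 0, top)), 0, top))
    return scores


def _picture_naming(overlap, age, cfg, rng) -> float:
    top = TASK_MAXIMA["picture_naming"]
    raw = (
        top
        - cfg.picture_naming_effect * overlap
        - cfg.age_slope * (age - cfg.mean_age)
        + (rng.normal(0.0, cfg.noise_sd_behavior) if cfg.noise_sd_behavior > 0 else 0.0)
    )
    return float(np.clip(np.rint(np.clip(raw, 0, top)), 0, top))


# ---- cohort ----------------------------------------------------------


def generate_cohort(cfg: SimulationConfig) -> Cohort:
    """Controls, lesioned patients, behavioral table and ground truth.

    Child seed streams: (volumes of controls, volumes of patients,
    demographics, behavioral noise, orientation noise) -- so the imaging
    data does not depend on the behavioral parameters.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_ctrl, s_pat, s_demo, s_beh, s_ori = [np.random.default_rng(s) for s in ss.spawn(5)]

    controls = [generate_control_volume(cfg, s_ctrl) for _ in range(cfg.n_controls)]

    patients, lesions = [], []
    for _ in range(cfg.n_patients):
        vol, les = generate_patient_volume(cfg, s_pat)
        patients.append(vol)
        lesions.append(les)

    crit = cfg.critical_mask()
    critical = Volume(crit.astype(np.uint8), cfg.affine(), space="template")
    denom = int(crit.sum())
    overlap = np.array([np.logical_and(l.data > 0, crit).sum() / denom for l in lesions])

    n = cfg.n_patients
    if n > 0:
        a = (cfg.age_range[0] - cfg.mean_age) / cfg.age_sd
        b = (cfg.age_range[1] - cfg.mean_age) / cfg.age_sd
        ages = stats.truncnorm.rvs(
            a, b, loc=cfg.mean_age, scale=cfg.age_sd, size=n, random_state=s_demo
        )
        handed = np.where(s_demo.random(n) < cfg.right_handed_frac, "R", "L")
    else:
        ages = np.zeros(0)
        handed = np.zeros(0, dtype=str)

    brain_vol_mm3 = float(cfg.brain_mask().sum()) * cfg.voxel_size_mm**3
    rows = []
    for i in range(n):
        scores = generate_behavior(overlap[i], ages[i], cfg, s_beh)
        pn = _picture_naming(overlap[i], ages[i], cfg, s_beh)
        les_vol = float((lesions[i].data > 0).sum()) * cfg.voxel_size_mm**3
        ori_raw = (
            cfg.orientation_max
            - cfg.orientation_effect * les_vol / brain_vol_mm3
            + (s_ori.normal(0.0, cfg.orientation_noise_sd) if cfg.orientation_noise_sd > 0 else 0.0)
        )
        ori = float(np.clip(np.rint(np.clip(ori_raw, 0, cfg.orientation_max)), 0, cfg.orientation_max))
        com = ndimage.center_of_mass(lesions[i].data)
        com_x = lesions[i].voxel_to_world(com)[0]
        hemisphere = "L" if com_x < -1.0 else ("R" if com_x > 1.0 else "B")
        rows.append(
            {
                "patient_id": f"P{i + 1:03d}",
                "age_years": float(ages[i]),
                "handedness": str(handed[i]),
                "hemisphere": hemisphere,
                **scores,
                "picture_naming": pn,
                "orientation_score": ori,
            }
        )
    columns = [
        "patient_id",
        "age_years",
        "handedness",
        "hemisphere",
        "gesture_production",
        "gesture_recognition",
        "gesture_imitation",
        "picture_naming",
        "orientation_score",
    ]
    table = pd.DataFrame(rows, columns=columns)

    truth = GroundTruth(lesions=lesions, critical_region=critical, overlap=overlap, config=cfg)
    return Cohort(controls=controls, patients=patients, table=table, truth=truth)
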