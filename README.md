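# ctvlsm

Automated stroke-lesion delineation from CT-like head volumes and
voxel-based lesion-symptom mapping (VLSM) of continuous praxis scores,
with a fully synthetic cohort generator so every stage is verifiable
against known ground truth.

## Who this is for

Researchers in stroke neuropsychology who want to relate lesion
anatomy to behavioral deficits (here: limb apraxia screened with
gesture production, gesture recognition, and meaningless gesture
imitation tasks) using clinical CT rather than research MRI.  Clinical
CT is ubiquitous on stroke admission but lacks the mature lesion-
delineation tooling of MRI; this package implements the full analysis
chain at desk scale and validates each statistical link in it.

## The method

**Lesion delineation.**  Patient and control volumes are preprocessed
identically: threshold-based background clustering at 0.1% of maximum
intensity (keeping the largest 26-connected component), a 12-parameter
affine registration to a template (normalized cross-correlation,
coarse-to-fine Powell search), an invertible logistic remap that
emphasizes the CSF/parenchyma contrast, brain and ventricle masks from
a two-class Otsu split with skull-stripping, 1-mm isotropic reslicing,
and 4-mm FWHM Gaussian smoothing (σ = FWHM / (2√(2 ln 2)) ≈ 1.699 mm).
Each patient voxel x\* is then scored against the k aligned controls
with the Crawford–Howell case–control statistic

    t = (x* − m̄) / (s · √((k+1)/k)),   df = k − 1,

which is exactly a pooled-variance two-sample t-test with group sizes
(k, 1).  The t map is thresholded one-tailed (hypo-intense for
ischemic, hyper-intense for hemorrhagic stroke; default p < 0.001)
and cleaned of clusters below 100 voxels, yielding a binary lesion map.

**Lesion–symptom mapping.**  At every voxel lesioned in ≥ 10 patients,
an OLS model relates the continuous task score to lesion status (0/1)
plus covariates of no interest (age, handedness, total lesion volume,
orientation score).  Per-voxel p values (one-sided for the deficit
direction) are corrected with Benjamini–Hochberg FDR at q = 0.05 over
exactly the tested voxels; significant voxels are reported as
26-connected clusters with volume, peak t, and peak world coordinates.

**Synthetic cohort.**  Controls are ellipsoidal brains (parenchyma
mean 40, CSF 10, smooth Gaussian noise); patients add one ellipsoidal
lesion with a signed intensity shift.  Behavioral scores follow
`clip(max − effect·overlap − age_slope·(age − 72.39) + noise, 0, max)`
rounded to each task's integer grid, where `overlap` is the lesion's
fractional coverage of a hidden critical region.  Demographics are
anchored to a large subacute stroke cohort (age ~ N(72.39, 12.8²)
truncated to [27, 94], 91% right-handed).

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_delineate_lesions.py
python analysis/03_vlsm_praxis.py
python analysis/04_behavioral_summary.py
```

(equivalently `ctvlsm all --out scratch/run --seed 2026`).  With the
default 60-patient cohort this prints:

```
median Dice vs ground truth: 0.748 (range 0.690-0.788)
gesture_production: 19356 voxels tested, 1577 significant, 2 cluster(s)
    cluster 1: 1576 mm^3, peak t=6.46 at (-12, -8, -0) mm
gesture_recognition: 19356 voxels tested, 0 significant, 0 cluster(s)
gesture_imitation: 19356 voxels tested, 1286 significant, 5 cluster(s)
    cluster 1: 1279 mm^3, peak t=5.65 at (-10, -12, 4) mm
composite apraxia vs orientation_score: r=0.322, p=0.0122
composite apraxia vs lesion_volume_mm3: r=-0.313, p=0.0151
composite apraxia vs age_years: r=-0.486, p=0.0001
```

Reading this: delineation recovers three quarters of each true lesion
by Dice overlap; the dominant VLSM clusters for production and
imitation peak a few millimetres from the hidden critical region
centred at (−8, −4, 2) mm, i.e. the mapping recovers the planted
lesion–deficit association; gesture recognition (score range only
0–6) is underpowered at n = 60, a realistic illustration of why such
studies need large cohorts.  The covariate correlations (orientation
positive, lesion volume and age negative against the composite apraxia
score) show the simulated nuisance structure the covariates are there
to absorb.

## Layout

- `src/ctvlsm/` — the library: `synthetic` (cohort generator),
  `preprocess` (CT chain), `delineate` (Crawford–Howell maps),
  `vlsm` (mass-univariate mapping + FDR), `behavior` (score semantics,
  cut-offs), `pipeline` / `cli` (orchestration), `experiments`
  (validation harnesses).
- `analysis/` — numbered drivers of the worked example.
- `docs/methods.md` — modeling assumptions, parameter choices,
  numerical details, and limitations.
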