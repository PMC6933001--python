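# Methods notes

This note records the models, parameter choices, numerical details and
known limitations of the `ctvlsm` pipeline.  Nothing here states an
empirical result that the test-suite or `scripts/acceptance.py` does
not itself compute.

## The statistical model

### Voxelwise outlier delineation

The lesion model treats each preprocessed patient volume as a single
case against a control sample of k aligned volumes.  At a voxel with
control sample mean m̄ and sample standard deviation s (divisor k−1),
the case–control statistic

t = (x\* − m̄) / (s √((k+1)/k)), df = k − 1

is Student-distributed under the null that the case is drawn from the
same Gaussian law as the controls.  It is algebraically identical to a
pooled-variance two-sample t-test with group sizes (k, 1); the suite
checks this identity to 1e−12.  Voxels with zero control variance
(e.g. background, which is exactly zero by construction) carry no
statistic and are excluded from all downstream steps rather than being
assigned infinite t.

Binarization is one-tailed: hypo-intense (negative tail) for ischemic
stroke, hyper-intense for hemorrhagic, either tail when the stroke
type is unknown.  The default threshold p < 0.001 and the 100-voxel
(0.1 mL) minimum cluster are configuration, not doctrine: the
threshold is not dictated by the delineation model itself, and both
are exposed in `DelineationConfig`.

### Mass-univariate lesion–symptom mapping

Per tested voxel, OLS of the continuous score on
[1, lesion(0/1), age, handedness(R=0/L=1), total lesion volume,
orientation score].  Implementation detail: the covariate block is
constant across voxels, so score and lesion columns are residualized
against it once (Frisch–Waugh) and each voxel reduces to a simple
regression; coefficients, t and p equal the full fit exactly (checked
against `statsmodels.OLS`).  Voxels whose lesion column is collinear
with the covariates (residual sum of squares of the lesion column
< 1e−8) are skipped and excluded from the FDR denominator — untested
voxels carry no p value.

The reported t map is oriented for the deficit direction (positive t =
lesion lowers the score), since every task is scored "higher =
better"; one-sided testing in that direction is the default, with a
two-sided option.  FDR is Benjamini–Hochberg within each task's
tested-voxel set separately; there is no cross-task correction because
the tasks are analysed as separate experiments.  Hemisphere is not a
covariate (left/right/bilateral patients are pooled); subgroup
analyses are row filters on the behavior table followed by a re-run,
not separate code.

### Behavioral score semantics

Task grids: gesture production 0–12 (6 items × 0/1/2), gesture
recognition 0–6 (6 × 0/1), meaningless gesture imitation 0–12
(4 × 0–3), picture naming 0–14.  Age-banded integer cut-offs
(bands <65 / 65–74 / ≥75) classify per-task impairment with the tie
rule "impaired iff score ≤ cut-off"; on the integer score grid this
reproduces the alternative fractional thresholds (11.5 / 5.8 / 11.5),
which ship as a second `CutoffTable`.  Whether a score exactly at the
cut-off counts as impaired is not decidable from the cut-off tables
alone; the ≤ rule is a documented package decision.  The composite
apraxia score is the sum of the three task scores each rescaled to
[0, 1] (range [0, 3]) — a package definition chosen for monotonicity
and equal task weighting, since no canonical formula exists.
Correlation p values are descriptive (no multiplicity correction).
A single-patient cohort reports SD as missing, not zero.

## The synthetic cohort: what it emulates, what it does not

The generator produces the statistical structure the analysis assumes,
not realistic neuroanatomy:

* **Geometry** — an ellipsoidal brain (default radii 20×22×20 mm on a
  48³ 1-mm grid, world origin at the grid centre, RAS+) with two
  interior ventricles.  One ellipsoidal lesion per patient (single,
  first-stroke lesions keep ground truth unambiguous), radii drawn
  uniformly from 9–15 mm, centre sampled uniformly among voxels deep
  enough that the lesion stays inside the brain.  Lesions exclude
  ventricular CSF voxels: infarcts damage tissue, and a lesion shift
  applied to CSF would drive intensities negative.
* **Intensities** — parenchyma 40 ± 2, CSF 10 ± 2 (arbitrary CT-like
  units), exact zero background, Gaussian noise with 2-mm spatial
  correlation (smoothed white noise rescaled to unit marginal SD via
  the kernel's root sum of squares).  Lesions shift intensity by −25
  (ischemic default) or a positive value (hemorrhagic).
* **Behavior** — score = clip(max − effect·overlap − 0.05·(age −
  72.39) + N(0, 1), 0, max), rounded to the task's integer grid, where
  overlap is |lesion ∩ critical region| / |critical region| against a
  hidden 7-mm-radius ellipsoid at (−8, −4, 2) mm.  Default effects are
  half the task range (6 / 3 / 6 points, picture naming 7).  The
  orientation covariate declines noisily with relative lesion volume
  (14 − 20·lesion/brain volume ratio + N(0, 1.5)), giving the
  qualitative covariate correlation structure a real cohort shows.
  This linear-in-overlap deficit model is an artifact of the
  generator, not a scientific claim: the target analysis is
  observational and specifies no generative model of deficits.
* **Demographics** — age ~ N(72.39, 12.80²) truncated to [27, 94];
  handedness Bernoulli(353/387).
* **Reproducibility** — one seed spawns independent child streams for
  control volumes, patient volumes, demographics, behavioral noise and
  orientation noise, so changing behavioral effect sizes leaves the
  imaging data bit-identical (this underlies the monotone-power
  experiment, which re-uses one delineation across effect scales).

Deliberate scale compromises: lesion/brain volume ratio is ~0.15
versus ~0.09 in a realistic cohort, because lesions must stay
resolvable relative to the 4-mm smoothing kernel at desk scale; the
constraint that lesions fit wholly inside the small brain concentrates
lesion centres medially, so lesion coverage is denser centrally than
in real stroke (where middle-cerebral-artery territory dominates).
Not emulated at all: CT physics (beam hardening, 4–5 mm slice
anisotropy, scanner differences), skull and scalp compartments,
atrophy, non-ellipsoidal lesion shapes, and multi-focal strokes.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated assumptions, not performance on clinical
CT.

## Preprocessing: numerical choices

* **Background removal** — voxels ≤ frac·max (frac = 0.001) are
  zeroed; 26-connected components; only the largest (the head) kept.
  An all-foreground volume is retained whole with a warning rather
  than erroring (degenerate-input rule).
* **Intensity remap** — f(x) = 100 / (1 + exp(−k(x − c))) with c
  midway between the CSF and parenchyma levels and k chosen so the
  two tissue modes sit at logit ±1.5 ("gain").  Closed-form inverse
  c + logit(y/100)/k; round-trip ≤ 1e−6 over the working intensity
  range.  The gain default is deliberately mild: saturating the modes
  inflates the contrast-to-noise ratio and thereby widens the halo of
  supra-threshold voxels that smoothing spreads around true lesion
  boundaries (the dominant Dice cost, see below).
* **Masks** — two-class Otsu split of within-head intensities; brain =
  hole-filled head foreground, ventricles = below-threshold interior
  (2-voxel erosion margin, ≥10-voxel components).  A flat or
  effectively one-class histogram (either class < 0.1% of head
  voxels) raises an error.
* **Transform convention** — `AffineTransform` (3 translations mm, 3
  rotations rad, 3 scales, 3 shears; matrix T·Rz·Ry·Rx·Shear·Scale)
  maps moving-volume world coordinates into template world
  coordinates; resampling is the pull-back through its inverse.
  Intensities resample trilinearly, masks nearest-neighbour.  Voxel
  indices are 0-based; world coordinates follow the NIfTI affine.
* **Registration** — normalized cross-correlation maximized by a
  deterministic coarse-to-fine Powell search (centre-of-mass
  translation init; translations+rotations on a 2× downsampled pair,
  then all 12 parameters coarse, then a full-resolution refinement
  with internal step scaling 1 mm / 0.01 rad / 1% / 0.01 per
  parameter class).  No stochastic restarts, so results are exactly
  reproducible.  Caveat measured by the recovery experiment: affine
  parameters of a *symmetric* ellipsoid are not identifiable
  (rotations trade off against shear and scale — the affine symmetry
  group of an ellipsoid is three-dimensional), so the validation
  phantom breaks symmetry with offset ventricles and strong smooth
  texture.
* **Smoothing** — separable Gaussian, σ_mm = FWHM/(2√(2 ln 2)) per
  axis converted to voxels via the affine spacing, kernel truncated at
  3σ and normalized to unit sum, zero-padded boundaries.  Truncation
  at 3σ (rather than a wider support) makes interior mass
  conservation exact for features ≥ 3σ from the volume edge.
* **Reslicing** — isotropic output grid over a world bounding box
  (default: the input field of view mapped through the transform);
  with an identity transform on an already-isotropic grid the sampling
  points coincide and the operation is exact.

## Validation experiments and their problem sizes

Problem sizes are the package's chosen desk-scale study conditions:

* **Null calibration** — 16 replicates, each an independent k = 30
  control set plus one lesion-free case on the 48³ grid, smoothed
  4 mm; rejection rates at α ∈ {0.05, 0.001} compared within 3
  Monte-Carlo SEs (replicate-level SE, which absorbs the within-map
  spatial correlation).  Calibration is run on the linear part of the
  pipeline (smoothing): smoothing preserves Gaussianity, so the
  statistic is exactly Student there.  The sigmoid remap is monotone
  but nonlinear and mildly skews the marginals; with the default gain
  this does not visibly move the realized rates, but exact calibration
  is only guaranteed for Gaussian inputs.
* **Lesion recovery** — 20 patients at default contrast (shift −25,
  parenchyma SD 2); median Dice against the true masks.  The
  systematic error is a ~2–3 mm halo outside the true boundary where
  the smoothed lesion signal still exceeds the detection threshold;
  Dice ≈ 2/(1 + ((r+d)/r)³) for lesion radius r and halo d, which is
  why the default lesion radii (9–15 mm) sit well above d.
* **VLSM recovery** — 100 patients, k = 30, effects at half task
  range, behavioral noise SD 1; each task must produce an
  FDR-significant cluster whose peak falls inside the 3-voxel-dilated
  critical region.
* **Error control** — 200 seeded score permutations; mean false-
  discovery proportion compared against q + 3 MC SE (under the full
  null every rejection is false, so per-replicate FDP is the indicator
  of any rejection).
* **Monotone power** — effect scales {0.25, 0.5, 1.0} × task range
  with identical seeds; significant-voxel counts must be
  non-decreasing.
* **Registration recovery** — 10 random affines (|translation| ≤ 10
  mm, |rotation| ≤ 0.1 rad, scales 0.9–1.1) on the asymmetric
  phantom; the template is synthesized from the moving image under the
  known transform so the metric's optimum lies exactly at the true
  parameters, isolating optimizer error from interpolation bias.
  Tolerances: 1 mm translation, 2% scale, 0.02 rad rotation (the
  rotation tolerance is the package's own, as no canonical figure
  exists).

## Known limitations

* Registration is validated on self-consistent synthetic pairs; no
  claim is made about cross-modality or cross-scanner robustness.
* The delineation threshold trades the detection halo against
  sensitivity; on low-contrast (small-shift) lesions Dice degrades
  smoothly toward zero, and no per-patient adaptive threshold is
  implemented.
* The uncorrected exploratory threshold mode (config switch) and
  subgroup re-runs are supported but carry no error-control guarantee.
* Anatomical labeling of cluster coordinates is out of scope: the
  cluster table ships an empty `area` column as a hook for
  user-supplied atlas label volumes.
* DICOM ingestion and visualization beyond the stored NIfTI maps are
  out of scope.
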