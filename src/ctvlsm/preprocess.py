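"""CT preprocessing chain.

Stages (in pipeline order): threshold-based background-cluster removal,
12-parameter affine registration to a template, an invertible sigmoid
intensity remap emphasizing the CSF/parenchyma contrast, brain and
ventricle masking with skull-stripping, isotropic reslicing into a
template bounding box, and Gaussian smoothing specified by FWHM.

Conventions
-----------
* An :class:`AffineTransform` maps *moving-volume world coordinates
  into template world coordinates*; resampling uses its inverse
  (pull-back), so ``resample(moving, T, reference)`` evaluates the
  moving image at ``T^{-1} @ A_ref @ i`` for each reference voxel ``i``.
* Intensity images are resampled trilinearly, masks nearest-neighbor.
* Cluster connectivity is the full 26-neighborhood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.special import expit, logit
from skimage.filters import threshold_otsu

from .volume import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "AffineTransform",
    "SigmoidParams",
    "default_sigmoid_params",
    "remove_background_clusters",
    "register_affine",
    "resample",
    "transform_intensity",
    "inverse_transform_intensity",
    "make_masks",
    "skull_strip",
    "reslice_isotropic",
    "smooth_gaussian",
    "fwhm_to_sigma",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: FWHM -> Gaussian sigma conversion factor, 1 / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm * FWHM_TO_SIGMA


# ---- background removal ---------------------------------------------


def remove_background_clusters(
    v: Volume, frac: float = 0.001, min_cluster_voxels: int | None = None
) -> Volume:
    """Zero sub-threshold voxels and keep only the head component.

    Voxels with intensity <= ``frac * max`` are zeroed; the remaining
    suprathreshold voxels are grouped by 26-connectivity and only the
    largest connected component (the head) is retained.  When
    ``min_cluster_voxels`` is given, all components of at least that
    size are kept instead of just the largest.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    data = np.asarray(v.data, dtype=float)
    if data.min() < 0:
        raise ValueError("expected non-negative intensities")
    if not data.any():
        raise ValueError("all-zero input: no foreground to retain")
    thresh = frac * data.max()
    fg = data > thresh
    if fg.all():
        logger.warning("no background below threshold; retaining full volume")
        warnings.warn("no background below threshold; retaining full volume", stacklevel=2)
        return v.copy()
    labels, n = ndimage.label(fg, structure=_CONN26)
    if n == 0:
        raise ValueError("no suprathreshold voxels")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    if min_cluster_voxels is None:
        keep = labels == int(np.argmax(counts))
    else:
        big = np.flatnonzero(counts >= min_cluster_voxels)
        keep = np.isin(labels, big)
    out = np.where(keep, data, 0.0)
    return v.with_data(out)


# ---- affine transform ------------------------------------------------

_IDENTITY_PARAMS = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)


@dataclass
class AffineTransform:
    """12-parameter affine: translations (mm), rotations (rad), scales, shears.

    The composed 4x4 matrix is ``T @ R @ Shear @ Scale`` with
    ``R = Rz @ Ry @ Rx``; identity parameters compose to the identity
    matrix.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    shear: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.scale = np.asarray(self.scale, dtype=float).reshape(3)
        self.shear = np.asarray(self.shear, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_vector(cls, vec) -> "AffineTransform":
        vec = np.asarray(vec, dtype=float).reshape(12)
        return cls(vec[0:3], vec[3:6], vec[6:9], vec[9:12])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.scale, self.shear])

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        hxy, hxz, hyz = self.shear
        Sh = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
        M = np.eye(4)
        M[:3, :3] = Rz @ Ry @ Rx @ Sh @ np.diag(self.scale)
        M[:3, 3] = self.translation
        if abs(np.linalg.det(M[:3, :3])) < 1e-12:
            raise ValueError("composed affine is singular")
        return M

    @property
    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def resample(moving: Volume, transform, reference: Volume, order: int = 1) -> Volume:
    """Resample ``moving`` onto ``reference``'s grid under ``transform``.

    ``transform`` is an :class:`AffineTransform` (moving world ->
    template world) or an equivalent 4x4 matrix; ``order`` 0 for masks,
    1 (trilinear) for intensities.
    """
    M = transform.matrix if isinstance(transform, AffineTransform) else np.asarray(transform, float)
    V = np.linalg.inv(moving.affine) @ np.linalg.inv(M) @ reference.affine
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=float),
        V[:3, :3],
        V[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )
    return Volume(out, reference.affine.copy(), reference.space)


# ---- registration ----------------------------------------------------

# internal optimizer step scaling: 1 unit = 1 mm / 0.01 rad / 1% scale / 0.01 shear
_PARAM_SCALES = np.array([1, 1, 1, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])


def _downsample(v: Volume, factor: int = 2) -> Volume:
    data = ndimage.gaussian_filter(np.asarray(v.data, float), sigma=factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    aff = v.affine.copy()
    aff[:3, :3] *= factor
    return Volume(data, aff, v.space)


def _neg_ncc(a: np.ndarray, b_centered: np.ndarray, b_norm: float) -> float:
    ac = a - a.mean()
    na = np.linalg.norm(ac)
    if na == 0 or b_norm == 0:
        return 1.0
    return -float(np.dot(ac.ravel(), b_centered.ravel()) / (na * b_norm))


def register_affine(
    moving: Volume,
    template: Volume,
    coarse_factor: int = 2,
    maxiter: int = 30,
) -> AffineTransform:
    """Estimate the 12-parameter affine aligning ``moving`` to ``template``.

    Maximizes normalized cross-correlation with a deterministic
    coarse-to-fine Powell search: translations+rotations on a
    downsampled pair, then all 12 parameters coarse, then a full-
    resolution refinement.  Initialization translates the moving
    center of mass onto the template's.
    """
    mov = np.asarray(moving.data, float)
    tpl = np.asarray(template.data, float)
    if mov.std() == 0 or tpl.std() == 0:
        raise ValueError("cannot register flat (constant-intensity) images")

    com_m = moving.voxel_to_world(ndimage.center_of_mass(np.abs(mov)))
    com_t = template.voxel_to_world(ndimage.center_of_mass(np.abs(tpl)))

    q = np.zeros(12)
    q[:3] = np.asarray(com_t) - np.asarray(com_m)

    def run_stage(mov_v, tpl_v, q_start, free, xtol):
        tpl_c = tpl_v.data - tpl_v.data.mean()
        tpl_n = float(np.linalg.norm(tpl_c))
        q_full = q_start.copy()

        def obj(q_free):
            qq = q_full.copy()
            qq[free] = q_free
            params = _IDENTITY_PARAMS + qq * _PARAM_SCALES
            t = AffineTransform.from_vector(params)
            r = resample(mov_v, t, tpl_v, order=1)
            return _neg_ncc(r.data, tpl_c, tpl_n)

        res = optimize.minimize(
            obj,
            q_full[free],
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-8, "maxiter": maxiter},
        )
        q_full[free] = res.x
        return q_full

    free6 = np.arange(6)
    free12 = np.arange(12)
    if coarse_factor and coarse_factor > 1:
        mov_c = _downsample(moving, coarse_factor)
        tpl_c = _downsample(template, coarse_factor)
        q = run_stage(mov_c, tpl_c, q, free6, xtol=0.05)
        q = run_stage(mov_c, tpl_c, q, free12, xtol=0.02)
    q = run_stage(moving, template, q, free12, xtol=2e-3)

    params = _IDENTITY_PARAMS + q * _PARAM_SCALES
    result = AffineTransform.from_vector(params)
    # sanity: the optimum must beat a flat field
    final = resample(moving, result, template, order=1)
    if final.data.std() == 0:
        raise ValueError("registration failed: transformed image is empty")
    return result


# ---- intensity transform ---------------------------------------------


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic intensity remap f(x) = out_max / (1 + exp(-slope (x - center))).

    Strictly increasing for slope > 0, steepest at ``center``; the
    closed-form inverse is ``center + logit(y / out_max) / slope``.
    """

    center: float
    slope: float
    out_max: float = 100.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive (strictly monotone mapping)")
        if self.out_max <= 0:
            raise ValueError("out_max must be positive")


def default_sigmoid_params(
    csf_level: float, parenchyma_level: float, gain: float = 1.5, out_max: float = 100.0
) -> SigmoidParams:
    """Remap centered midway between CSF and parenchyma levels.

    ``gain`` places the tissue modes at logit +/- gain; the default 1.5
    gives a mild contrast emphasis without saturating either mode
    (strong saturation would widen the detected-lesion halo that
    smoothing introduces around true lesion boundaries).
    """
    if parenchyma_level <= csf_level:
        raise ValueError("parenchyma level must exceed CSF level")
    center = 0.5 * (csf_level + parenchyma_level)
    slope = 2.0 * gain / (parenchyma_level - csf_level)
    return SigmoidParams(center=center, slope=slope, out_max=out_max)


def transform_intensity(v: Volume, params: SigmoidParams) -> Volume:
    """Forward sigmoid remap of the intensities (order-preserving)."""
    out = params.out_max * expit(params.slope * (np.asarray(v.data, float) - params.center))
    return v.with_data(out)


def inverse_transform_intensity(v: Volume, params: SigmoidParams) -> Volume:
    """Closed-form inverse of :func:`transform_intensity`."""
    ratio = np.asarray(v.data, float) / params.out_max
    if np.any(ratio <= 0) or np.any(ratio >= 1):
        raise ValueError("values outside the open range (0, out_max); not in the image of the forward map")
    return v.with_data(params.center + logit(ratio) / params.slope)


# ---- masks and skull-stripping ---------------------------------------


def make_masks(v: Volume, foreground: np.ndarray | None = None) -> tuple[Volume, Volume]:
    """Brain and ventricle masks from the intensity distribution.

    A two-class Otsu split over within-head voxels separates CSF-level
    from parenchyma-level intensities.  The brain mask is the filled
    head foreground; the ventricle mask is the below-threshold interior.
    Raises when the within-head histogram cannot be split into two
    classes (flat or effectively unimodal input).
    """
    data = np.asarray(v.data, dtype=float)
    fg = np.asarray(foreground, bool) if foreground is not None else data > 0
    if fg.sum() < 10:
        raise ValueError("empty (or near-empty) volume: no head foreground")
    vals = data[fg]
    if np.ptp(vals) == 0:
        raise ValueError("unimodal intensity distribution: cannot separate CSF from parenchyma")
    try:
        thresh = threshold_otsu(vals)
    except ValueError as exc:  # single-valued input
        raise ValueError("unimodal intensity distribution: cannot separate CSF from parenchyma") from exc
    low_frac = float((vals < thresh).mean())
    if min(low_frac, 1.0 - low_frac) < 1e-3:
        raise ValueError("intensity histogram effectively unimodal: degenerate class split")

    brain = ndimage.binary_fill_holes(fg)
    interior = ndimage.binary_erosion(brain, iterations=2)
    vent = (data < thresh) & interior
    # drop speckle components
    labels, n = ndimage.label(vent, structure=_CONN26)
    if n:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        vent = np.isin(labels, np.flatnonzero(counts >= 10))
    return (
        Volume(brain.astype(np.uint8), v.affine.copy(), v.space),
        Volume(vent.astype(np.uint8), v.affine.copy(), v.space),
    )


def skull_strip(v: Volume, brain_mask: Volume) -> Volume:
    """Zero voxels outside the brain mask; inside voxels are unchanged."""
    if not v.same_grid(brain_mask):
        raise ValueError("volume and mask are on different grids")
    if not brain_mask.is_mask():
        raise ValueError("brain_mask must be binary")
    return v.with_data(np.asarray(v.data, float) * (brain_mask.data > 0))


# ---- reslicing -------------------------------------------------------


def _default_bounding_box(v: Volume, t: AffineTransform):
    shape = np.asarray(v.shape) - 1
    corners = np.array(
        [[i, j, k] for i in (0, shape[0]) for j in (0, shape[1]) for k in (0, shape[2])],
        dtype=float,
    )
    world = np.asarray(v.voxel_to_world(corners))
    hom = np.c_[world, np.ones(len(world))]
    mapped = (t.matrix @ hom.T).T[:, :3]
    return mapped.min(axis=0), mapped.max(axis=0)


def reslice_isotropic(
    v: Volume,
    t: AffineTransform | None = None,
    resolution_mm: float = 1.0,
    bounding_box=None,
    is_mask: bool = False,
) -> Volume:
    """Resample into template space on an isotropic grid over a bounding box.

    ``bounding_box`` is ``((xmin, ymin, zmin), (xmax, ymax, zmax))`` in
    template-world mm; by default the input field of view mapped through
    ``t``.  Intensities use trilinear interpolation, masks nearest-
    neighbor.  A bounding box that excludes the whole head triggers a
    warning rather than an error.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    t = t or AffineTransform.identity()
    if bounding_box is None:
        lo, hi = _default_bounding_box(v, t)
    else:
        lo = np.asarray(bounding_box[0], dtype=float)
        hi = np.asarray(bounding_box[1], dtype=float)
    shape = tuple(int(np.round((hi[i] - lo[i]) / resolution_mm)) + 1 for i in range(3))
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * resolution_mm
    affine[:3, 3] = lo
    reference = Volume(np.zeros(shape), affine, space="template")
    out = resample(v, t, reference, order=0 if is_mask else 1)
    if v.data.any() and not out.data.any():
        warnings.warn("bounding box appears to exclude the brain entirely", stacklevel=2)
    out.space = "template"
    return out


# ---- smoothing -------------------------------------------------------


def smooth_gaussian(v: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing specified by FWHM in mm.

    sigma_mm = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxels via
    the affine spacing.  The discrete kernel is truncated at 3 sigma and
    normalized to sum 1, with zero-padded boundaries, so interior mass
    is conserved.  fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return v.copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / v.spacing
    out = ndimage.gaussian_filter(
        np.asarray(v.data, dtype=float), sigma=sigma_vox, mode="constant", cval=0.0, truncate=3.0
    )
    return v.with_data(out)
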