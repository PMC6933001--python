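"""Automated lesion delineation by voxelwise case-control outlier statistics.

Each preprocessed patient volume is compared voxel-by-voxel to the
normal intensity range defined by a set of aligned control volumes
using the Crawford-Howell case-control t statistic

    t = (x* - mean) / (s * sqrt((k + 1) / k)),    df = k - 1,

where ``x*`` is the patient's voxel intensity and mean/s are the
control sample mean and standard deviation (divisor k - 1).  The
resulting t-score map codes the degree of abnormality of each voxel
and is thresholded (one-tailed Student p, in the hypo- or
hyper-intense direction for ischemic vs hemorrhagic stroke) into a
binary lesion map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats

from .volume import Volume

__all__ = [
    "ControlSet",
    "TScoreMap",
    "crawford_howell_t",
    "tscore_map",
    "binarize_lesion",
    "lesion_volume",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ControlSet:
    """Per-voxel normal intensity law from k aligned control volumes."""

    mean: Volume
    sd: Volume  # sample sd, divisor k - 1
    k: int

    @classmethod
    def from_volumes(cls, volumes) -> "ControlSet":
        volumes = list(volumes)
        if len(volumes) < 2:
            raise ValueError("need at least 2 control volumes")
        ref = volumes[0]
        for v in volumes[1:]:
            if not v.same_grid(ref):
                raise ValueError("control volumes are on different grids")
        stack = np.stack([np.asarray(v.data, float) for v in volumes])
        return cls(
            mean=ref.with_data(stack.mean(axis=0)),
            sd=ref.with_data(stack.std(axis=0, ddof=1)),
            k=len(volumes),
        )

    @property
    def df(self) -> int:
        return self.k - 1


@dataclass
class TScoreMap:
    """Voxelwise abnormality t map with constant df = k - 1.

    ``valid`` flags voxels with positive control sd; elsewhere the
    statistic is undefined and the t map holds NaN.
    """

    t: Volume
    df: int
    valid: Volume


def crawford_howell_t(case_value: float, control_values) -> tuple[float, int]:
    """Single-case vs control-sample t statistic and its df.

    Positive when the case exceeds the control mean.  Identical to a
    pooled-variance two-sample t-test with group sizes (k, 1).
    """
    controls = np.asarray(control_values, dtype=float)
    k = controls.size
    if k < 2:
        raise ValueError("need at least 2 controls (df = k - 1 >= 1)")
    s = controls.std(ddof=1)
    if s == 0:
        raise ValueError("zero control variance: statistic undefined")
    t = (float(case_value) - controls.mean()) / (s * np.sqrt((k + 1) / k))
    return float(t), k - 1


def tscore_map(patient: Volume, controls: ControlSet) -> TScoreMap:
    """Vectorized Crawford-Howell t at every voxel with positive control sd."""
    if not patient.same_grid(controls.mean):
        raise ValueError("patient volume is not on the control grid")
    k = controls.k
    sd = np.asarray(controls.sd.data, float)
    valid = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (np.asarray(patient.data, float) - controls.mean.data) / (sd * np.sqrt((k + 1) / k))
    t[~valid] = np.nan
    return TScoreMap(
        t=patient.with_data(t),
        df=k - 1,
        valid=patient.with_data(valid.astype(np.uint8)),
    )


def binarize_lesion(
    tmap: TScoreMap,
    direction: str = "hypo",
    alpha: float = 0.001,
    brain_mask: Volume | None = None,
    min_lesion_cluster: int = 100,
) -> Volume:
    """Threshold a t-score map into a binary lesion map.

    A voxel is lesioned when its one-tailed Student p (df = k - 1) is
    below ``alpha`` in the requested direction: ``hypo`` (negative tail,
    ischemic), ``hyper`` (positive tail, hemorrhagic) or ``both``
    (either tail, each at ``alpha``).  The map is intersected with the
    brain mask and 26-connected clusters smaller than
    ``min_lesion_cluster`` voxels are removed.
    """
    if direction not in ("hypo", "hyper", "both"):
        raise ValueError("direction must be 'hypo', 'hyper' or 'both'")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    crit = stats.t.isf(alpha, tmap.df)
    t = np.asarray(tmap.t.data, float)
    with np.errstate(invalid="ignore"):
        if direction == "hypo":
            sig = t < -crit
        elif direction == "hyper":
            sig = t > crit
        else:
            sig = np.abs(t) > crit
    sig &= tmap.valid.data > 0
    if brain_mask is not None:
        if not brain_mask.same_grid(tmap.t):
            raise ValueError("brain mask grid mismatch")
        sig &= brain_mask.data > 0
    if min_lesion_cluster > 1 and sig.any():
        labels, n = ndimage.label(sig, structure=_CONN26)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        sig = np.isin(labels, np.flatnonzero(counts >= min_lesion_cluster))
    return tmap.t.with_data(sig.astype(np.uint8))


def lesion_volume(lesion: Volume) -> float:
    """Volume of a binary lesion map in mm^3 (voxel count x voxel volume)."""
    if not lesion.is_mask():
        raise ValueError("lesion map must be binary")
    return float((lesion.data > 0).sum()) * lesion.voxel_volume_mm3
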