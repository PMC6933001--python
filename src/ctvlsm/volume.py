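"""Shared 3-D volume container.

A :class:`Volume` couples a scalar 3-D array with a 4x4 voxel-to-world
affine (mm, RAS+ orientation), mirroring the NIfTI-1 convention.  It is
the carrier for CT-like images, t-score maps, and binary masks
throughout the pipeline.  Voxel indices are 0-based; world coordinates
follow the affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Volume", "dice"]


@dataclass
class Volume:
    data: np.ndarray
    affine: np.ndarray
    space: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    # ---- geometry ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size along each axis in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, idx) -> np.ndarray:
        """Map voxel indices (i, j, k) -> world coordinates (x, y, z) mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        out = (self.affine @ hom.T).T[:, :3]
        return out[0] if out.shape[0] == 1 else out

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        hom = np.c_[xyz, np.ones(len(xyz))]
        out = (np.linalg.inv(self.affine) @ hom.T).T[:, :3]
        return out[0] if out.shape[0] == 1 else out

    # ---- bookkeeping ------------------------------------------------
    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), self.space)

    def with_data(self, data: np.ndarray, space: str | None = None) -> "Volume":
        return Volume(np.asarray(data), self.affine.copy(), space or self.space)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=atol)
        )

    def is_mask(self) -> bool:
        """True when the volume contains only values in {0, 1}."""
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    # ---- I/O --------------------------------------------------------
    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, space: str = "native") -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine, space)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two binary masks.

    Accepts :class:`Volume` or array input; both empty -> 1.0.
    """
    a = (a.data if isinstance(a, Volume) else np.asarray(a)) > 0
    b = (b.data if isinstance(b, Volume) else np.asarray(b)) > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
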