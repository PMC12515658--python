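"""Computational domain: a labeled voxel grid with anisotropic physical spacing.

The domain is the brain extracted from structural MRI and segmented into
cerebrospinal fluid (CSF), gray matter and white matter; everything outside
the brain (skull, air) is BACKGROUND.  Tumor cells migrate through gray and
white matter only — CSF and BACKGROUND carry zero diffusivity and zero cell
density, which is how the no-flux boundary at the skull and ventricles is
realized.

Axis order is (x, y, slice): the third axis is the slice direction, whose
spacing in clinical surveillance scans (≈7 mm) is much coarser than the
in-plane resolution (≈0.9 mm).  Voxel indices are 0-based.  Inputs are
assumed co-registered, so affine orientation beyond voxel spacing is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["TissueLabel", "VoxelGrid"]


class TissueLabel(IntEnum):
    """Integer tissue codes used in label volumes (fixed code table)."""

    BACKGROUND = 0
    CSF = 1
    GRAY = 2
    WHITE = 3


VALID_LABELS = frozenset(int(l) for l in TissueLabel)


@dataclass
class VoxelGrid:
    """A 3-D labeled voxel grid with physical spacing in millimetres.

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Per-voxel tissue code (:class:`TissueLabel`).
    spacing : tuple of float
        Physical voxel size (in-plane, in-plane, slice) in mm.  The slice
        spacing may exceed the in-plane spacing (anisotropy is the norm).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = self.labels
            if not np.all(lab == np.round(lab)):
                raise ValueError("labels must be integer codes")
            self.labels = lab.astype(np.uint8)
        bad = set(np.unique(self.labels).tolist()) - VALID_LABELS
        if bad:
            raise ValueError(
                f"invalid tissue label code(s) {sorted(bad)}; "
                f"expected codes {sorted(VALID_LABELS)} "
                "(0=BACKGROUND, 1=CSF, 2=GRAY, 3=WHITE)"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals in mm, got {self.spacing}")
        if not self.tissue_mask.any():
            raise ValueError("degenerate grid: no GRAY or WHITE voxel")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(n) for n in self.labels.shape)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def tissue_mask(self) -> np.ndarray:
        """Boolean mask of GRAY or WHITE voxels (where cells may live)."""
        return (self.labels == TissueLabel.GRAY) | (self.labels == TissueLabel.WHITE)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates, origin at the grid center."""
        axes = [
            (np.arange(n, dtype=float) - (n - 1) / 2.0) * h
            for n, h in zip(self.dims, self.spacing)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return self.dims == other.dims and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )
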