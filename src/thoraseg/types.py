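"""Shared in-memory containers for volumes, labels and masks.

Axis convention
---------------
All 3-D arrays are indexed ``(z, y, x)`` with ``z = 0`` the most caudal
axial slice and ``z`` increasing cranially; ``(y, x)`` spans the axial
plane.  Voxels are isotropic; spacing is carried in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Integer label codes shared by the phantom generator and the pipeline.
OUTSIDE = 0
LUNG = 1
INTERMEDIATE = 2
SOFT = 3
BONE = 4
DIAPHRAGM = 5

#: Canonical legend mapping label code -> tissue-class name.
LABEL_LEGEND: dict[int, str] = {
    OUTSIDE: "outside",
    LUNG: "lung",
    INTERMEDIATE: "intermediate",
    SOFT: "soft",
    BONE: "bone",
    DIAPHRAGM: "diaphragm",
}

#: The three density classes reported as percentages of the thoracic cavity.
TISSUE_CLASSES = ("lung", "intermediate", "soft")


@dataclass
class CtVolume:
    """A 3-D grayscale CT volume with isotropic voxel spacing.

    Intensities are arbitrary units (the pipeline thresholds and clusters
    data-adaptively, so only the density ordering matters, not a
    Hounsfield calibration).
    """

    data: np.ndarray  # float array, shape (nz, ny, nx)
    voxel_size_mm: float = 0.1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3 dimensions, got {self.data.ndim}"
            )
        if self.data.shape[0] < 8:
            raise ValueError(
                f"volume needs at least 8 axial slices, got {self.data.shape[0]}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer-coded per-voxel classes with a legend.

    Every voxel carries exactly one label and the legend covers every
    integer present in ``labels``.
    """

    labels: np.ndarray  # int array, shape (nz, ny, nx)
    legend: dict[int, str] = field(default_factory=lambda: dict(LABEL_LEGEND))
    voxel_size_mm: float = 0.1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover label codes {sorted(missing)}")
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean mask of all voxels whose legend entry equals ``name``."""
        codes = [c for c, n in self.legend.items() if n == name]
        return np.isin(self.labels, codes)


@dataclass
class ThoracicMask:
    """Per-slice filled thoracic-cavity region derived from the ribcage.

    ``mask`` is the final (pass-2, bone-free) cavity; the pass-1 mask and
    per-slice diagnostics are kept so refinement behaviour is inspectable.
    """

    mask: np.ndarray  # bool, (nz, ny, nx)
    slice_centroids: np.ndarray  # (nz, 2) float, (y, x); NaN where empty
    region_counts: np.ndarray  # (nz,) int, rib regions found per slice
    pass1_mask: np.ndarray | None = None

    @property
    def nonempty_slices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.any(axis=(1, 2)))
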