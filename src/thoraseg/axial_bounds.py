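"""Cranial/caudal bounding of the thoracic cavity and diaphragm removal.

The cranial cutoff is the most cranial axial slice at which the tracheal
air column (the lung-class region nearest the mask centroid in the
cranial quarter of the scan) has split into the two main bronchi.  The
heart–diaphragm interface is the slice whose cavity contains the highest
percentage of lung.  The diaphragm is then traced caudal of that
interface column-by-column: the inflection of each (x, y) intensity
z-trace — the steepest descending gradient from soft (sub-diaphragmatic)
to lung density — marks the dome surface, and everything caudal of it is
removed from the tissue counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .density_cluster import TissueSegmentation
from .types import LUNG, OUTSIDE, CtVolume, ThoracicMask

log = logging.getLogger(__name__)


@dataclass
class AxialBounds:
    """Cranial (tracheal bifurcation) and interface slice indices."""

    z_cranial: int
    z_interface: int
    n_slices_used: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.z_interface < self.z_cranial:
            raise ValueError(
                f"need 0 <= z_interface < z_cranial, got "
                f"interface={self.z_interface}, cranial={self.z_cranial}"
            )


@dataclass
class DiaphragmMask:
    """Binary diaphragm voxels between the caudal scan end and z_interface."""

    mask: np.ndarray  # bool (nz, ny, nx)
    z_interface: int


def cranial_cutoff(
    seg: TissueSegmentation,
    mask: ThoracicMask,
    min_airway_px: int = 4,
    search_fraction: float = 0.25,
) -> int:
    """Most cranial slice where the tracheal region splits in two.

    Scans caudally from the cranial end through the cranial
    ``search_fraction`` of nonempty mask slices.  Per slice, lung-class
    components of at least ``min_airway_px`` pixels whose centroids lie
    within half the cavity's equivalent radius of the mask centroid are
    taken as the tracheal structure; the first slice with exactly two such
    components is the bifurcation (restricting the search to the cranial
    quarter avoids mistaking paired structures deep in the lung for it).
    """
    zs = mask.nonempty_slices
    if len(zs) == 0:
        raise ValueError("thoracic mask is empty")
    z_top = zs[-1]
    n_search = max(3, int(np.ceil(search_fraction * len(zs))))
    window = [z for z in zs[::-1][:n_search]]
    for z in window:
        m = mask.mask[z]
        area = m.sum()
        if area == 0:
            continue
        cy, cx = ndi.center_of_mass(m)
        r_eq = np.sqrt(area / np.pi)
        lung2d = (seg.classes[z] == LUNG) & m
        lab, n = ndi.label(lung2d)
        central = 0
        for j in range(1, n + 1):
            comp = lab == j
            if comp.sum() < min_airway_px:
                continue
            gy, gx = ndi.center_of_mass(comp)
            if np.hypot(gy - cy, gx - cx) <= 0.5 * r_eq:
                central += 1
        if central == 2:
            return int(z)
    raise ValueError(
        "tracheal bifurcation not detected in the cranial slices; "
        "pass an explicit cutoff (config z_cranial / --z-cranial) to override"
    )


def heart_diaphragm_interface(seg: TissueSegmentation, mask: ThoracicMask) -> int:
    """Slice with the highest per-slice lung percentage of the cavity.

    Ties break toward the most caudal slice.
    """
    m = mask.mask
    cav = m.sum(axis=(1, 2))
    if not cav.any():
        raise ValueError("thoracic mask is empty")
    lung = ((seg.classes == LUNG) & m).sum(axis=(1, 2))
    frac = np.where(cav > 0, lung / np.maximum(cav, 1), -1.0)
    return int(np.argmax(frac))  # first maximum = most caudal


def segment_diaphragm(
    v: CtVolume,
    mask: ThoracicMask,
    z_interface: int,
    smoothing_window: int = 5,
) -> DiaphragmMask:
    """Per-column z-trace inflection segmentation of the diaphragm dome.

    Each in-mask (x, y) column's intensity trace from the caudal scan end
    to ``z_interface`` is smoothed with a centred moving average
    (``smoothing_window`` slices) and the inflection is placed at the
    steepest descending gradient — the soft-to-lung transition at the dome
    surface.  Everything caudal of (and including) the inflection is
    diaphragm.  Columns with no descending gradient, or whose smoothed
    dynamic range is below noise (< 2 MADs of the raw trace), contribute
    nothing.
    """
    nz = v.shape[0]
    out = np.zeros(v.shape, dtype=bool)
    if z_interface <= 0:
        warnings.warn("z_interface at the caudal end: empty diaphragm mask")
        return DiaphragmMask(out, z_interface)
    sub = v.data[: z_interface + 1]  # (nzz, ny, nx)
    nzz = sub.shape[0]
    w = min(smoothing_window, nzz)
    smooth = ndi.uniform_filter1d(sub, size=w, axis=0, mode="nearest")
    grad = np.gradient(smooth, axis=0)
    z_star = np.argmin(grad, axis=0)  # steepest descent per column
    min_grad = np.min(grad, axis=0)
    rng_sm = smooth.max(axis=0) - smooth.min(axis=0)
    med = np.median(sub, axis=0)
    mad = np.median(np.abs(sub - med[None]), axis=0)
    col_ok = (min_grad < 0) & (rng_sm >= 2.0 * mad)
    col_in_mask = mask.mask[: z_interface + 1].any(axis=0)
    col_ok &= col_in_mask
    zz = np.arange(nzz)[:, None, None]
    caudal = zz <= z_star[None]
    out[: z_interface + 1] = caudal & col_ok[None] & mask.mask[: z_interface + 1]
    return DiaphragmMask(out, z_interface)


def apply_bounds(
    seg: TissueSegmentation, bounds: AxialBounds, d: DiaphragmMask
) -> TissueSegmentation:
    """Relabel voxels cranial of the cutoff and all diaphragm voxels outside.

    What remains defines the reported thoracic cavity, so tumors sitting
    cranial of the dome surface stay in the counts.
    """
    if d.mask.shape != seg.classes.shape:
        raise ValueError("diaphragm mask grid does not match segmentation grid")
    classes = seg.classes.copy()
    classes[bounds.z_cranial + 1 :] = OUTSIDE
    classes[d.mask] = OUTSIDE
    return TissueSegmentation(classes, seg.model, voxel_size_mm=seg.voxel_size_mm)
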