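"""End-to-end orchestration of the segmentation pipeline.

``run_mlast`` chains: bone threshold → largest 3-D component → slice
stacking → two-pass thoracic mask → scan-wide 1-D k-means → tissue
classification → tracheal cranial cutoff → heart–diaphragm interface →
diaphragm removal → tissue percentages of the thoracic cavity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import axial_bounds as ab
from . import cavity_mask as cm
from . import density_cluster as dc
from .types import INTERMEDIATE, LUNG, SOFT, CtVolume

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters with the published defaults."""

    bone_threshold: float | str = "auto"
    connectivity: int = 26
    stack_window: int = 3
    refine_fraction: float = 0.3
    k_clusters: int = 3
    max_iter: int = 100
    restarts: int = 3
    min_region_px: int = 3
    min_regions: int = 3
    min_airway_px: int = 4
    smoothing_window: int = 5
    z_cranial: int | None = None  # manual override when bifurcation detection fails
    seed: int = 0

    #: fields and defaults, used for config-file validation
    @classmethod
    def defaults(cls) -> dict:
        return {f.name: f.default for f in dataclasses.fields(cls)}

    def validate(self) -> None:
        errs = []
        if self.bone_threshold != "auto":
            try:
                float(self.bone_threshold)
            except (TypeError, ValueError):
                errs.append(f"bone_threshold: expected 'auto' or a number, got {self.bone_threshold!r}")
        if self.connectivity not in (6, 18, 26):
            errs.append(f"connectivity: must be 6, 18 or 26, got {self.connectivity}")
        if self.stack_window < 1 or self.stack_window % 2 == 0:
            errs.append(f"stack_window: must be a positive odd integer, got {self.stack_window}")
        if not 0 < self.refine_fraction <= 1:
            errs.append(f"refine_fraction: must lie in (0, 1], got {self.refine_fraction}")
        if self.k_clusters < 2:
            errs.append(f"k_clusters: must be >= 2, got {self.k_clusters}")
        if self.max_iter < 1:
            errs.append(f"max_iter: must be >= 1, got {self.max_iter}")
        if self.restarts < 1:
            errs.append(f"restarts: must be >= 1, got {self.restarts}")
        for name in ("min_region_px", "min_regions", "min_airway_px", "smoothing_window"):
            if getattr(self, name) < 1:
                errs.append(f"{name}: must be >= 1, got {getattr(self, name)}")
        if errs:
            raise ValueError("invalid configuration: " + "; ".join(errs))


@dataclass
class SegmentationResult:
    """Tissue composition of the bounded, diaphragm-free thoracic cavity."""

    scan_id: str
    counts: dict[str, int]  # lung / intermediate / soft voxel counts
    voxel_size_mm: float
    bounds: ab.AxialBounds
    model: dc.ClusterModel
    n_diaphragm_voxels: int = 0
    mask_voxels_in_bounds: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pct(self, tissue: str) -> float:
        return 100.0 * self.counts[tissue] / self.total

    @property
    def pct_lung(self) -> float:
        return self.pct("lung")

    @property
    def pct_intermediate(self) -> float:
        return self.pct("intermediate")

    @property
    def pct_soft(self) -> float:
        return self.pct("soft")

    @property
    def combined_burden_pct(self) -> float:
        """Soft + intermediate percentage — the tumor-burden readout."""
        return self.pct_soft + self.pct_intermediate

    def volume_mm3(self, tissue: str) -> float:
        return self.counts[tissue] * self.voxel_size_mm**3

    def row(self) -> dict:
        """One ResultTable row (see volume_io.write_results)."""
        return {
            "scan_id": self.scan_id,
            "pct_lung": self.pct_lung,
            "pct_soft": self.pct_soft,
            "pct_intermediate": self.pct_intermediate,
            "vol_lung_mm3": self.volume_mm3("lung"),
            "vol_soft_mm3": self.volume_mm3("soft"),
            "vol_intermediate_mm3": self.volume_mm3("intermediate"),
            "z_cranial": self.bounds.z_cranial,
            "z_interface": self.bounds.z_interface,
            "n_slices": self.bounds.n_slices_used,
        }


def run_mlast(
    v: CtVolume,
    cfg: PipelineConfig | None = None,
    scan_id: str = "scan",
    return_intermediates: bool = False,
):
    """Run the full pipeline on one scan.

    Deterministic given ``(v, cfg)`` — all randomness (k-means++ seeding)
    flows from ``cfg.seed``.  With ``return_intermediates`` the thoracic
    mask, tissue segmentation, bounded segmentation and diaphragm mask are
    returned alongside the result for inspection or overlay rendering.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    def _stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except ValueError as e:
            raise ValueError(f"[{name}] {e}") from e
        return out

    mask = _stage("cavity_mask", cm.build_thoracic_mask, v, cfg)
    log.info("%s: mask covers %d voxels over %d slices",
             scan_id, int(mask.mask.sum()), len(mask.nonempty_slices))

    values = v.data[mask.mask]
    model = _stage(
        "density_cluster", dc.fit_kmeans, values,
        k=cfg.k_clusters, max_iter=cfg.max_iter, restarts=cfg.restarts, rng=rng,
    )
    log.info("%s: centroids %s after %d iterations (converged=%s, sse=%.4g)",
             scan_id, np.round(model.centroids, 4), model.n_iterations,
             model.converged, model.objective)
    seg = _stage("classify", dc.classify_tissue, v, mask, model)

    if cfg.z_cranial is not None:
        z_cranial = int(cfg.z_cranial)
    else:
        z_cranial = _stage("cranial_cutoff", ab.cranial_cutoff, seg, mask,
                           min_airway_px=cfg.min_airway_px)
    z_interface = _stage("interface", ab.heart_diaphragm_interface, seg, mask)
    if z_interface >= z_cranial:
        raise ValueError(
            f"[bounds] interface slice {z_interface} not caudal of cutoff {z_cranial}"
        )
    dia = _stage("diaphragm", ab.segment_diaphragm, v, mask, z_interface,
                 smoothing_window=cfg.smoothing_window)
    z_lo = int(mask.nonempty_slices[0])
    bounds = ab.AxialBounds(
        z_cranial=z_cranial, z_interface=z_interface,
        n_slices_used=z_cranial - z_lo + 1,
    )
    bounded = _stage("apply_bounds", ab.apply_bounds, seg, bounds, dia)

    sub = bounded.classes
    counts = {
        "lung": int((sub == LUNG).sum()),
        "intermediate": int((sub == INTERMEDIATE).sum()),
        "soft": int((sub == SOFT).sum()),
    }
    if sum(counts.values()) == 0:
        raise ValueError("[fractions] no cavity voxels remain inside bounds")
    in_bounds = int(mask.mask[: z_cranial + 1].sum())
    n_dia = int(dia.mask[: z_cranial + 1].sum())
    result = SegmentationResult(
        scan_id=scan_id,
        counts=counts,
        voxel_size_mm=v.voxel_size_mm,
        bounds=bounds,
        model=model,
        n_diaphragm_voxels=n_dia,
        mask_voxels_in_bounds=in_bounds,
    )
    log.info("%s: lung %.2f%% / intermediate %.2f%% / soft %.2f%% of %d voxels",
             scan_id, result.pct_lung, result.pct_intermediate, result.pct_soft,
             result.total)
    if return_intermediates:
        return result, dict(mask=mask, seg=seg, bounded=bounded, diaphragm=dia)
    return result
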