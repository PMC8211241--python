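"""Synthetic mouse-thorax CT phantoms with exact ground-truth labels.

The phantom emulates the anatomy the segmentation pipeline relies on:

* a closed ribcage — helical rib arcs attached to a dorsal spine column
  and a cranial inlet ring, so the whole cage is one 3-D connected
  object of bone density;
* an elliptical thoracic cavity per axial slice, capped caudally by a
  diaphragm dome of soft density (the dome is solid: everything caudal
  of its upper surface — diaphragm muscle plus the abdominal tissue it
  rests on — is binned as "diaphragm", which is exactly the material the
  pipeline's z-trace inflection removes);
* two lung fields whose cross-section peaks at the dome apex, wrapped in
  a thin intermediate-density rim standing in for ground-glass margins
  and vessel partial volume;
* a soft-density heart ellipsoid between the lungs, so tumor-free
  phantoms still carry a realistic ~35–40 % soft-tissue fraction;
* a single tracheal air column cranial of the carina that splits into
  two separated bronchi caudal of it — the cue for the cranial cutoff;
* optional spherical tumors that overwrite lung voxels.

Densities are arbitrary units ordered lung < intermediate < soft < bone;
only the ordering matters because the pipeline thresholds and clusters
adaptively per scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .types import (
    BONE,
    DIAPHRAGM,
    INTERMEDIATE,
    LABEL_LEGEND,
    LUNG,
    OUTSIDE,
    SOFT,
    CtVolume,
    LabelVolume,
)

DEFAULT_TISSUE_MEANS = {"lung": 0.05, "intermediate": 0.35, "soft": 0.55, "bone": 1.0}
_AIR_MEAN = 0.02


@dataclass(frozen=True)
class Tumor:
    """A spherical lesion injected into the lung field."""

    center: tuple[float, float, float]  # (x, y, z) voxel coordinates
    radius_vox: float
    tissue: str = "soft"  # "soft" or "intermediate"

    def __post_init__(self) -> None:
        if self.tissue not in ("soft", "intermediate"):
            raise ValueError(f"tumor tissue must be soft or intermediate, got {self.tissue!r}")
        if not self.radius_vox > 0:
            raise ValueError("tumor radius must be positive")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic thorax.

    ``grid_shape`` is ``(nx, ny, nz)``; generated arrays are indexed
    ``(z, y, x)``.  ``cavity_radii`` are the base axial-plane semi-axes
    ``(a, b)`` of the thoracic cavity (x and y half-widths, voxels); the
    profile tapers mildly toward the cranial end.  ``dome_curvature`` is
    the number of slices the diaphragm dome falls between its apex and
    the cavity wall.
    """

    grid_shape: tuple[int, int, int] = (160, 160, 120)
    voxel_size_mm: float = 0.1
    tissue_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    noise_sd: float | dict[str, float] = 0.03
    rib_count: int = 5  # ribs per side visible in a mid-thorax slice
    rib_thickness_vox: float = 2.0
    cavity_radii: tuple[float, float] | None = None  # default 0.285*nx, 0.275*ny
    trachea_bifurcation_z: int | None = None  # default ~78 % of nz
    diaphragm_apex_z: int | None = None  # default ~33 % of nz
    dome_curvature: float | None = None  # default 0.31*nz slices of fall
    lung_fill: float = 1.0  # scales lung-field cross-section (burden dial-down)
    tumors: list[Tumor] = field(default_factory=list)
    motion_blur_sd: float = 0.0
    seed: int = 0

    # --- derived geometry -------------------------------------------------
    def resolved(self) -> "PhantomSpec":
        """Return a copy with all optional geometry filled in and validated."""
        nx, ny, nz = self.grid_shape
        spec = dataclasses.replace(
            self,
            cavity_radii=self.cavity_radii or (0.285 * nx, 0.275 * ny),
            trachea_bifurcation_z=(
                self.trachea_bifurcation_z
                if self.trachea_bifurcation_z is not None
                else round(0.78 * nz)
            ),
            diaphragm_apex_z=(
                self.diaphragm_apex_z
                if self.diaphragm_apex_z is not None
                else round(0.33 * nz)
            ),
            dome_curvature=(
                self.dome_curvature if self.dome_curvature is not None else 0.31 * nz
            ),
        )
        spec.validate()
        return spec

    def validate(self) -> None:
        nx, ny, nz = self.grid_shape
        if min(nx, ny, nz) < 48:
            raise ValueError(f"grid_shape too small for thorax geometry: {self.grid_shape}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        means = [self.tissue_means[k] for k in ("lung", "intermediate", "soft", "bone")]
        if not all(a < b for a, b in zip(means, means[1:])):
            raise ValueError(
                "tissue_means must be strictly increasing lung < intermediate < soft < bone"
            )
        sds = (
            self.noise_sd.values() if isinstance(self.noise_sd, dict) else [self.noise_sd]
        )
        if any(sd < 0 for sd in sds):
            raise ValueError("noise_sd must be nonnegative")
        if self.rib_count < 2:
            raise ValueError("rib_count must be at least 2")
        if not self.rib_thickness_vox > 0:
            raise ValueError("rib_thickness_vox must be positive")
        if not 0 < self.lung_fill <= 1.2:
            raise ValueError("lung_fill must lie in (0, 1.2]")
        a, b = self.cavity_radii
        margin = 3.0 + self.rib_thickness_vox + 1.0
        if a + margin >= nx / 2 - 1 or b + margin + 6 >= ny / 2 + 0.35 * ny:
            raise ValueError(
                f"ribcage around cavity_radii={self.cavity_radii} exceeds grid {self.grid_shape}"
            )
        if self.cage_z[1] >= nz or self.cage_z[0] < 0:
            raise ValueError("ribcage z-extent exceeds grid")
        if not (
            self.cage_z[0]
            < self.diaphragm_apex_z
            < self.trachea_bifurcation_z
            <= self.cage_z[1] - 3
        ):
            raise ValueError(
                "need cage bottom < diaphragm_apex_z < trachea_bifurcation_z < cage top; "
                f"got apex={self.diaphragm_apex_z}, bifurcation={self.trachea_bifurcation_z}"
            )
        if self.diaphragm_apex_z - self.dome_curvature < self.cage_z[0] - 6:
            raise ValueError("diaphragm dome falls caudal of the ribcage")

    @property
    def cage_z(self) -> tuple[int, int]:
        """Caudal and cranial slice of the ribcage."""
        nz = self.grid_shape[2]
        return round(0.067 * nz), nz - 1 - round(0.067 * nz)

    @property
    def center_xy(self) -> tuple[float, float]:
        return self.grid_shape[0] / 2.0, self.grid_shape[1] / 2.0

    def cavity_profile(self) -> np.ndarray:
        """Per-slice cavity semi-axes, shape (nz, 2): columns (a, b)."""
        nx, ny, nz = self.grid_shape
        a0, b0 = self.cavity_radii
        z0, z1 = self.cage_z
        scale = np.ones(nz)
        z = np.arange(nz)
        top_start = z1 - round(0.30 * nz)
        sel = z > top_start
        scale[sel] = 1.0 - 0.28 * (z[sel] - top_start) / max(z1 - top_start, 1)
        bot_end = z0 + round(0.10 * nz)
        sel = z < bot_end
        scale[sel] = 1.0 - 0.06 * (bot_end - z[sel]) / max(bot_end - z0, 1)
        return np.column_stack([a0 * scale, b0 * scale])


def _ellipse(yy, xx, cx, cy, a, b):
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _disk(yy, xx, cx, cy, r):
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[CtVolume, LabelVolume]:
    """Generate a synthetic thorax scan and its exact label volume.

    Deterministic given ``(spec, seed)``; the label geometry depends only
    on ``spec``, while the seed drives the intensity noise.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nx, ny, nz = spec.grid_shape
    cx, cy = spec.center_xy
    z0, z1 = spec.cage_z
    apex = spec.diaphragm_apex_z
    bif = spec.trachea_bifurcation_z
    prof = spec.cavity_profile()
    a0, b0 = spec.cavity_radii

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    labels = np.full((nz, ny, nx), OUTSIDE, dtype=np.int16)
    body = np.zeros((nz, ny, nx), dtype=bool)

    # Diaphragm dome upper surface: z_dome(x, y) = apex - curvature * rho^2,
    # rho normalized to the base cavity ellipse.  The dome is solid.
    rho2 = ((xx - cx) / a0) ** 2 + ((yy - cy) / b0) ** 2
    z_dome = apex - spec.dome_curvature * rho2
    dia_thickness = 1.5

    # Lung-field geometry (two ellipses per slice).  Cross-sectional area
    # tapers gently cranial of the dome apex so the per-slice lung fraction
    # peaks at the apex — the heart–diaphragm interface cue.
    fields_top = bif - max(3, round(0.05 * nz))
    lung_dx, lung_dy = 0.44 * a0, -0.02 * b0
    lung_ax, lung_ay = 0.74 * a0, 1.02 * b0

    # Heart: soft ellipsoid resting on the dome between the lungs.
    heart_rz = 0.14 * nz
    heart_c = (cx - 0.04 * nx, cy - 0.10 * ny, apex + heart_rz - 2.0)
    heart_rx, heart_ry = 0.28 * a0, 0.44 * b0

    trachea_xy = (cx, cy + 0.10 * b0)
    trachea_r = 3.0
    bronchus_sep = 5.5
    bronchus_r = 2.5

    # The animal fills most of the field of view, as in a real acquisition
    # (the bone threshold's Otsu-above-median rule relies on soft tissue,
    # not air, dominating the upper half of the intensity distribution).
    body_a = nx / 2 - 4.0
    body_b = ny / 2 - 4.0

    cavity = np.zeros((nz, ny, nx), dtype=bool)
    lung_fields = np.zeros((nz, ny, nx), dtype=bool)

    zz = np.arange(nz)[:, None, None]
    body[:] = _ellipse(yy, xx, cx, cy, body_a, body_b)[None]
    dome_solid = body & (zz <= z_dome[None] + dia_thickness) & (zz >= z0)

    for z in range(z0, z1 + 1):
        a, b = prof[z]
        foot = _ellipse(yy, xx, cx, cy, a, b)
        cav = foot & (z > z_dome + dia_thickness)
        cavity[z] = cav
        if z <= fields_top:
            up, down = max(z - apex, 0), max(apex - z, 0)
            s = spec.lung_fill * max(0.0, 1.0 - (2.4 * up + 1.44 * down) / nz)
            if s > 0:
                r = np.sqrt(s)
                for sx in (-1.0, 1.0):
                    lf = _ellipse(
                        yy, xx, cx + sx * lung_dx, cy + lung_dy, lung_ax * r, lung_ay * r
                    )
                    lung_fields[z] |= lf & foot

    # Heart carve-out (soft overwrites lung).
    heart = (
        ((xx[None] - heart_c[0]) / heart_rx) ** 2
        + ((yy[None] - heart_c[1]) / heart_ry) ** 2
        + ((zz - heart_c[2]) / heart_rz) ** 2
    ) <= 1.0
    lung_fields &= ~heart

    labels[cavity] = SOFT
    labels[lung_fields] = LUNG
    # Intermediate rim: the outer shell of the lung fields (ground-glass
    # margins, vessel partial volume).
    # in-plane erosion: the rim tracks the lateral lung margin, not the
    # near-horizontal dome face
    eroded = ndi.binary_erosion(
        lung_fields, structure=np.ones((1, 3, 3), dtype=bool), iterations=3
    )
    labels[lung_fields & ~eroded] = INTERMEDIATE

    # Airways: one trachea column cranial of the carina, two bronchi caudal.
    tr = _disk(yy, xx, trachea_xy[0], trachea_xy[1], trachea_r)
    br = _disk(yy, xx, trachea_xy[0] - bronchus_sep, trachea_xy[1], bronchus_r) | _disk(
        yy, xx, trachea_xy[0] + bronchus_sep, trachea_xy[1], bronchus_r
    )
    for z in range(fields_top + 1, bif + 1):
        labels[z][br & cavity[z]] = LUNG
    for z in range(bif + 1, z1 + 1):
        labels[z][tr & cavity[z]] = LUNG

    labels[dome_solid] = DIAPHRAGM

    # Tumors overwrite lung (and rim) voxels inside their spheres; a thin
    # intermediate shell rings soft lesions.
    for i, t in enumerate(spec.tumors):
        tx, ty, tz = t.center
        if not (
            0 <= round(tz) < nz
            and 0 <= round(ty) < ny
            and 0 <= round(tx) < nx
        ) or labels[round(tz), round(ty), round(tx)] not in (LUNG, INTERMEDIATE, SOFT):
            raise ValueError(f"tumor {i} centered outside the thoracic cavity: {t.center}")
        if (
            tx - t.radius_vox < 0
            or tx + t.radius_vox >= nx
            or ty - t.radius_vox < 0
            or ty + t.radius_vox >= ny
            or tz - t.radius_vox < 0
            or tz + t.radius_vox >= nz
        ):
            raise ValueError(f"tumor {i} exceeds the grid: {t.center}, r={t.radius_vox}")
        d2 = (xx[None] - tx) ** 2 + (yy[None] - ty) ** 2 + (zz - tz) ** 2
        sphere = d2 <= t.radius_vox**2
        editable = np.isin(labels, (LUNG, INTERMEDIATE))
        code = SOFT if t.tissue == "soft" else INTERMEDIATE
        labels[sphere & editable] = code
        if t.tissue == "soft":
            shell = (d2 <= (t.radius_vox + 1.5) ** 2) & ~sphere
            labels[shell & (labels == LUNG)] = INTERMEDIATE

    # --- ribcage (bone overwrites everything) ----------------------------
    bone = np.zeros((nz, ny, nx), dtype=bool)
    n_tracks = 2 * spec.rib_count
    # rib tracks sweep gently with z; the dorsal sector is left to the spine
    theta0 = np.deg2rad(115.0 + (395.0 - 115.0) * (np.arange(n_tracks) + 0.5) / n_tracks)
    sweep = np.deg2rad(18.0)
    for z in range(z0, z1 + 1):
        a, b = prof[z]
        frac = (z - z0) / max(z1 - z0, 1)
        th = theta0 + sweep * frac
        rx, ry = a + 2.5, b + 2.5
        for t in th:
            bone[z] |= _disk(
                yy, xx, cx + rx * np.cos(t), cy + ry * np.sin(t), spec.rib_thickness_vox
            )
        # dorsal spine column, tangent to the cavity
        bone[z] |= _disk(yy, xx, cx, cy + b + 4.5, 3.5)
    # thoracic-inlet ring ties ribs and spine into one 3-D component
    for z in range(z1 - 2, z1 + 1):
        a, b = prof[z]
        ring = _ellipse(yy, xx, cx, cy, a + 5.0, b + 5.0) & ~_ellipse(
            yy, xx, cx, cy, a + 1.0, b + 1.0
        )
        bone[z] |= ring
    if bone.any():
        edges = (
            bone[:, 0, :].any() or bone[:, -1, :].any()
            or bone[:, :, 0].any() or bone[:, :, -1].any()
        )
        if edges:
            raise ValueError("ribcage touches the grid boundary; enlarge grid_shape")
    labels[bone] = BONE

    # --- intensities ------------------------------------------------------
    means = spec.tissue_means
    mean_of = {
        LUNG: means["lung"],
        INTERMEDIATE: means["intermediate"],
        SOFT: means["soft"],
        BONE: means["bone"],
        DIAPHRAGM: means["soft"],
    }
    if isinstance(spec.noise_sd, dict):
        sd_of = {
            LUNG: spec.noise_sd.get("lung", 0.0),
            INTERMEDIATE: spec.noise_sd.get("intermediate", 0.0),
            SOFT: spec.noise_sd.get("soft", 0.0),
            BONE: spec.noise_sd.get("bone", 0.0),
            DIAPHRAGM: spec.noise_sd.get("soft", 0.0),
        }
        sd_air = spec.noise_sd.get("soft", 0.0)
    else:
        sd_of = {c: float(spec.noise_sd) for c in mean_of}
        sd_air = float(spec.noise_sd)

    mean_img = np.full(labels.shape, _AIR_MEAN)
    sd_img = np.full(labels.shape, sd_air)
    outside_body = (labels == OUTSIDE) & body
    mean_img[outside_body] = means["soft"]
    for code, m in mean_of.items():
        sel = labels == code
        mean_img[sel] = m
        sd_img[sel] = sd_of[code]
    intens = mean_img + rng.standard_normal(labels.shape) * sd_img
    if spec.motion_blur_sd > 0:
        intens = ndi.gaussian_filter(intens, sigma=(0.0, spec.motion_blur_sd, spec.motion_blur_sd))

    vol = CtVolume(intens, voxel_size_mm=spec.voxel_size_mm)
    lab = LabelVolume(labels, legend=dict(LABEL_LEGEND), voxel_size_mm=spec.voxel_size_mm)
    return vol, lab


def random_phantom_spec(
    rng: np.random.Generator, grid_shape: tuple[int, int, int] = (160, 160, 120)
) -> PhantomSpec:
    """A randomized-but-valid thorax geometry, for robustness testing.

    Varies cavity size, rib count, bifurcation and dome-apex levels over
    the anatomically plausible ranges the generator supports.
    """
    nx, ny, nz = grid_shape
    apex = int(rng.integers(round(0.30 * nz), round(0.38 * nz) + 1))
    cage_lo = round(0.067 * nz)
    return PhantomSpec(
        grid_shape=grid_shape,
        cavity_radii=(
            0.285 * nx * rng.uniform(0.95, 1.05),
            0.275 * ny * rng.uniform(0.97, 1.03),
        ),
        trachea_bifurcation_z=int(rng.integers(round(0.75 * nz), round(0.82 * nz) + 1)),
        diaphragm_apex_z=apex,
        # dome depth cannot outrun the caudal end of the ribcage
        dome_curvature=min(0.31 * nz, apex - (cage_lo - 6) - 1),
        rib_count=int(rng.integers(4, 7)),
        seed=int(rng.integers(2**31 - 1)),
    )


def with_tumor_load(spec: PhantomSpec, total_mm3: float) -> PhantomSpec:
    """Spec copy carrying ~``total_mm3`` of spherical tumors in the lungs.

    Spheres are placed at fixed sites along both lung fields (centred on
    the lung ellipses, spread cranially from the dome apex), largest
    first, so increasing ``total_mm3`` strictly grows the injected lesion
    volume while every site stays inside the lung field.  Spheres only
    overwrite lung-field voxels, so the realised volume can be somewhat
    smaller than nominal once lesions outgrow the local lung.
    """
    spec = spec.resolved()
    if total_mm3 <= 0:
        return dataclasses.replace(spec, tumors=[])
    nx, ny, nz = spec.grid_shape
    cx, cy = spec.center_xy
    a0, b0 = spec.cavity_radii
    apex = spec.diaphragm_apex_z
    dz = max(4, round(0.065 * nz))
    sites = [
        (cx + side * 0.44 * a0, cy - 0.02 * b0, apex + k * dz)
        for k in range(5)
        for side in (-1, 1)
    ]
    remaining = total_mm3 / spec.voxel_size_mm**3  # voxels
    r_cap = 0.09 * min(nx, ny)
    tumors = []
    for sx, sy, sz in sites:
        if remaining <= 0:
            break
        r = min(r_cap, (3.0 * remaining / (4.0 * np.pi)) ** (1.0 / 3.0))
        if r < 2.0:
            r = 2.0
        tumors.append(Tumor(center=(sx, sy, sz), radius_vox=float(r)))
        remaining -= 4.0 / 3.0 * np.pi * r**3
    return dataclasses.replace(spec, tumors=tumors)


def ground_truth_fractions(labels: LabelVolume, bounds=None) -> dict[str, float]:
    """True tissue percentages of the cavity, optionally z-bounded.

    Counts lung / intermediate / soft voxels (diaphragm and outside are
    excluded by construction) caudal of and including ``bounds.z_cranial``
    when bounds are given.  Percentages sum to 100.
    """
    lab = labels.labels
    nz = lab.shape[0]
    z_hi = nz - 1
    if bounds is not None:
        z_hi = int(getattr(bounds, "z_cranial", bounds))
        if not 0 <= z_hi < nz:
            raise ValueError(f"bounds z_cranial={z_hi} outside volume z range [0, {nz})")
    sub = lab[: z_hi + 1]
    counts = {
        "lung": int((sub == LUNG).sum()),
        "intermediate": int((sub == INTERMEDIATE).sum()),
        "soft": int((sub == SOFT).sum()),
    }
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no cavity voxels within bounds")
    return {k: 100.0 * v / total for k, v in counts.items()}
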