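"""Reading and writing volumes, label maps, result tables and configs.

All format dialects live here; the algorithmic modules only see
:class:`~thoraseg.types.CtVolume` / :class:`~thoraseg.types.LabelVolume`
arrays in the internal caudal→cranial ``(z, y, x)`` convention.  I/O is
pure plumbing: nothing here alters intensities or labels beyond dtype
promotion and axis reordering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .pipeline import PipelineConfig
from .types import LABEL_LEGEND, CtVolume, LabelVolume

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "scan_id",
    "pct_lung",
    "pct_soft",
    "pct_intermediate",
    "vol_lung_mm3",
    "vol_soft_mm3",
    "vol_intermediate_mm3",
    "z_cranial",
    "z_interface",
    "n_slices",
]

_NIFTI_EXT = (".nii", ".nii.gz")
_TIFF_EXT = (".tif", ".tiff")


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    name = path.name.lower()
    if any(name.endswith(e) for e in _NIFTI_EXT):
        return "nifti"
    if any(name.endswith(e) for e in _TIFF_EXT):
        return "tiff"
    raise ValueError(f"cannot infer format from extension of {path}")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_volume(
    path, voxel_size_mm: float | None = None, fmt: str | None = None, kind: str = "intensity"
):
    """Read a 3-D volume from NIfTI-1 or multipage TIFF.

    NIfTI spacing comes from the header (must be isotropic within 1 %); if
    the affine's z axis points caudally the data are flipped to the
    internal caudal→cranial convention and the flip is logged.  TIFF
    spacing comes from a JSON sidecar or the ``voxel_size_mm`` argument,
    defaulting to 0.1 mm with a logged warning.  ``kind`` selects an
    intensity (:class:`CtVolume`) or label (:class:`LabelVolume`) read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path, fmt)
    legend = None
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)  # (x, y, z)
        if data.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {data.ndim} in {path}")
        zooms = img.header.get_zooms()[:3]
        if max(zooms) - min(zooms) > 0.01 * max(zooms):
            raise ValueError(f"anisotropic spacing beyond 1%: {zooms}")
        spacing = float(zooms[0])
        if voxel_size_mm is not None:
            spacing = voxel_size_mm
        arr = np.transpose(data, (2, 1, 0))  # -> (z, y, x)
        if img.affine[2, 2] < 0:
            arr = arr[::-1]
            log.info("flipped %s to caudal→cranial z", path.name)
    else:
        data = tifffile.imread(str(path))  # (z, y, x)
        if data.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {data.ndim} in {path}")
        arr = data
        spacing = voxel_size_mm
        side = _sidecar(path)
        if spacing is None and side.exists():
            meta = json.loads(side.read_text())
            spacing = float(meta.get("voxel_size_mm"))
        if spacing is None:
            spacing = 0.1
            log.warning("no spacing for %s; assuming 0.1 mm isotropic", path.name)
    if kind == "labels":
        legend = dict(LABEL_LEGEND)
        side = _sidecar(path)
        if side.exists():
            meta = json.loads(side.read_text())
            if "legend" in meta:
                legend = {int(k): v for k, v in meta["legend"].items()}
        return LabelVolume(np.asarray(arr).astype(np.int16), legend=legend,
                           voxel_size_mm=spacing)
    return CtVolume(np.ascontiguousarray(arr, dtype=np.float64), voxel_size_mm=spacing)


def write_volume(v: CtVolume | LabelVolume, path, fmt: str | None = None) -> None:
    """Write a volume losslessly to NIfTI-1 or multipage TIFF.

    TIFF output gets a JSON sidecar carrying the spacing (and, for label
    volumes, the legend).
    """
    path = Path(path)
    fmt = _format_of(path, fmt)
    is_labels = isinstance(v, LabelVolume)
    arr = v.labels if is_labels else v.data
    spacing = v.voxel_size_mm
    if fmt == "nifti":
        data = np.transpose(arr, (2, 1, 0))  # (x, y, z), z already caudal→cranial
        affine = np.diag([spacing, spacing, spacing, 1.0])
        img = nib.Nifti1Image(np.asarray(data), affine)
        img.header.set_zooms((spacing,) * 3)
        nib.save(img, str(path))
        if is_labels:
            _sidecar(path).write_text(json.dumps({"legend": v.legend}))
    else:
        tifffile.imwrite(str(path), np.asarray(arr))
        meta = {"voxel_size_mm": spacing}
        if is_labels:
            meta["legend"] = v.legend
        _sidecar(path).write_text(json.dumps(meta))


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV with the fixed column order."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table missing columns {missing}")
    table[RESULT_COLUMNS].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a result table CSV back into a DataFrame."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table missing columns {missing}")
    return df[RESULT_COLUMNS]


def read_config(path) -> PipelineConfig:
    """Read a flat YAML/JSON mapping into a validated PipelineConfig.

    Unknown keys are rejected and every schema violation is named.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a flat key→value mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def write_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
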