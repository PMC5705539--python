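"""NIfTI-1 volume I/O with a unit sidecar, plus CSV table helpers.

Volumes are written as NIfTI-1 with a diagonal affine built from the voxel
size (mm, grid-corner origin); the physical unit travels both in the NIfTI
``descrip`` header field and in a small JSON sidecar next to the image.
Masks are stored as 8-bit 0/1 volumes.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VALID_UNITS, VOIMask, VoxelGrid
from .quantify import RCTable

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as NIfTI-1 plus a JSON sidecar carrying the unit tag."""
    path = Path(path)
    affine = np.diag([*grid.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(grid.values.astype(np.float64), affine)
    img.header["descrip"] = f"unit={grid.unit}".encode()
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"unit": grid.unit, "voxel_size_mm": list(grid.voxel_size_mm)})
    )


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a NIfTI-1 volume; the unit comes from the sidecar or header."""
    path = Path(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: geometry metadata missing or invalid (zooms={zooms})")
    unit = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        unit = json.loads(sidecar.read_text()).get("unit")
    if unit is None:
        descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
        if descrip.startswith("unit="):
            unit = descrip[len("unit="):]
    if unit is None or unit not in VALID_UNITS:
        warnings.warn(f"{path}: no unit tag found; using 'unknown'", stacklevel=2)
        unit = "unknown"
    values = np.asarray(img.dataobj, dtype=float)
    return VoxelGrid(values, tuple(float(z) for z in zooms), unit)


def write_mask(mask: VOIMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit 0/1 NIfTI volume."""
    path = Path(path)
    affine = np.diag([*mask.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header["descrip"] = b"unit=mask"
    img.header.set_zooms(mask.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VOIMask:
    path = Path(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    values = np.asarray(img.dataobj)
    return VOIMask(values > 0, tuple(float(z) for z in zooms))


def write_rc_table(table: RCTable, path: str | Path) -> None:
    pd.DataFrame({"volume_mL": table.volumes_mL, "rc": table.rc}).to_csv(
        path, index=False
    )


def read_rc_table(path: str | Path) -> RCTable:
    df = pd.read_csv(path)
    return RCTable(df["volume_mL"].to_numpy(), df["rc"].to_numpy())


def write_stats_csv(stats: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"stat": list(stats.keys()), "value": list(stats.values())}
    ).to_csv(path, index=False)
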