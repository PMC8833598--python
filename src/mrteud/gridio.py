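"""Grid and table I/O: NRRD/NIfTI voxel grids, CSV tables, run logs.

NRRD is the native on-disk format (self-describing spacing/origin); NIfTI is
accepted through the same SimpleITK path.  Arrays are stored in the package's
(x, y, z) axis order by transposing SimpleITK's (z, y, x) buffers, so
written-then-read grids are bit-identical in values and geometry.
"""

from __future__ import annotations

import json
import re
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk

from .errors import ConfigError, InputError
from .geometry import LabelGrid, VoxelGrid

__all__ = [
    "read_grid",
    "write_grid",
    "read_labels",
    "write_labels",
    "write_run_log",
    "packaged_data_path",
]

_SUPPORTED = (".nrrd", ".nhdr", ".nii", ".nii.gz")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED):
        raise ConfigError(f"unsupported grid format {path.name!r}; use NRRD or NIfTI")


def write_grid(grid: VoxelGrid, path) -> Path:
    """Write a VoxelGrid to NRRD or NIfTI (by extension)."""
    path = Path(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(path))
    return path


def read_grid(path) -> VoxelGrid:
    """Read an NRRD or NIfTI scalar grid into a VoxelGrid."""
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise InputError(f"grid file not found: {path}")
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return VoxelGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", label)


def write_labels(labels: LabelGrid, directory) -> dict[str, Path]:
    """Write one uint8 NRRD per structure plus a JSON index mapping labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index: dict[str, str] = {}
    paths: dict[str, Path] = {}
    for name, mask in labels.masks.items():
        fname = f"label_{_safe_name(name)}.nrrd"
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(mask.transpose(2, 1, 0).astype(np.uint8))
        )
        img.SetSpacing(tuple(labels.spacing))
        img.SetOrigin(tuple(labels.origin))
        sitk.WriteImage(img, str(directory / fname))
        index[name] = fname
        paths[name] = directory / fname
    (directory / "labels.json").write_text(json.dumps(index, indent=2))
    return paths


def read_labels(directory) -> LabelGrid:
    """Read a labelmap set written by :func:`write_labels`."""
    directory = Path(directory)
    index_path = directory / "labels.json"
    if not index_path.exists():
        raise InputError(f"no labels.json index in {directory}")
    index = json.loads(index_path.read_text())
    masks = {}
    spacing = origin = None
    for name, fname in index.items():
        img = sitk.ReadImage(str(directory / fname))
        masks[name] = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(bool)
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
    if not masks:
        raise InputError(f"empty labelmap index in {directory}")
    return LabelGrid(masks, spacing, origin)


def write_run_log(directory, command: str, parameters: Mapping, seed: int | None = None) -> Path:
    """Versioned, machine-readable record of a CLI run."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    log = {
        "package": "mrteud",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "parameters": parameters,
    }
    path = directory / "run.json"
    path.write_text(json.dumps(log, indent=2, default=str))
    return path


def packaged_data_path(name: str) -> Path:
    """Path to a CSV shipped with the package (tissue table, constraints)."""
    path = Path(__file__).parent / "data" / name
    if not path.exists():
        raise ConfigError(f"no packaged data file {name!r}")
    return path
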