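"""Optional DICOM RT import (read-only): RT-Dose grids and RT-Struct contours.

Isolated so the core never requires DICOM inputs; the importers produce the
package's own :class:`VoxelGrid`/:class:`LabelGrid` containers.  Contours are
rasterized per axial slice with a point-in-polygon test on voxel centres.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pydicom

from .errors import InputError
from .geometry import LabelGrid, VoxelGrid

__all__ = ["read_rt_dose", "read_rt_struct"]


def _as_dataset(path_or_dataset) -> pydicom.Dataset:
    if isinstance(path_or_dataset, pydicom.Dataset):
        return path_or_dataset
    return pydicom.dcmread(str(path_or_dataset))


def read_rt_dose(path_or_dataset) -> VoxelGrid:
    """RT-Dose pixel data, scaled to Gy, as a VoxelGrid.

    Requires a uniform ``GridFrameOffsetVector``; the DICOM frame order
    (frames, rows, columns) = (z, y, x) is transposed to (x, y, z).
    """
    ds = _as_dataset(path_or_dataset)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise InputError("dataset is not an RT-Dose object")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector], dtype=float)
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise InputError("non-uniform RT-Dose frame spacing is not supported")
    sz = float(dz[0]) if offsets.size > 1 else 1.0
    sy, sx = (float(v) for v in ds.PixelSpacing)  # row spacing (y), column spacing (x)
    ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
    return VoxelGrid(arr.transpose(2, 1, 0), (sx, sy, sz), (ox, oy, oz + float(offsets[0])))


def read_rt_struct(path_or_dataset, reference: VoxelGrid) -> LabelGrid:
    """Rasterize RT-Struct contours onto the reference grid as labelmaps."""
    from matplotlib.path import Path as MplPath  # lazy: plotting stack is optional here

    ds = _as_dataset(path_or_dataset)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise InputError("dataset is not an RT-Struct object")
    roi_names: Mapping[int, str] = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    nx, ny, nz = reference.shape
    ox, oy, oz = reference.origin
    sx, sy, sz = reference.spacing
    xs = ox + sx * np.arange(nx)
    ys = oy + sy * np.arange(ny)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([XX.ravel(), YY.ravel()], axis=1)

    masks: dict[str, np.ndarray] = {}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        name = roi_names.get(int(roi_contour.ReferencedROINumber))
        if name is None:
            continue
        mask = np.zeros((nx, ny, nz), dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            if data.shape[0] < 3:
                continue
            k = int(round((float(data[0, 2]) - oz) / sz))
            if not 0 <= k < nz:
                continue
            inside = MplPath(data[:, :2]).contains_points(pts).reshape(nx, ny)
            mask[:, :, k] |= inside
        masks[name] = mask
    if not masks:
        raise InputError("RT-Struct contains no rasterizable contours")
    return LabelGrid(masks, reference.spacing, reference.origin)
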