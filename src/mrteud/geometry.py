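"""Voxel grids, structure labelmaps, conformal apertures and beam arrangement.

Conventions
-----------
Right-handed patient-like axes with 0-based indices and voxel-centre
sampling: array axis 0 = x, 1 = y, 2 = z (mm).  ``origin`` is the physical
coordinate of the centre of voxel (0, 0, 0).  Gantry rotation is about the z
axis (coplanar beams only); at gantry angle 0 the beam travels along -y and
the angle increases counter-clockwise in the axial (x, y) plane:

    direction(theta) = (sin t, -cos t, 0)
    lateral(theta)   = (cos t,  sin t, 0)      # beam's-eye lateral axis

The microbeam lattice of a field runs along the lateral axis, with a peak
plane anchored at the isocenter (zero phase offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InputError

__all__ = [
    "VoxelGrid",
    "LabelGrid",
    "FieldMask",
    "beam_axes",
    "resample_double_xy",
    "resample_labels_double_xy",
    "project_target",
    "dilate_mask",
    "arrange_beams",
]


@dataclass
class VoxelGrid:
    """3-D scalar field (density relative to water, or dose in Gy)."""

    values: np.ndarray
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, centre of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError("VoxelGrid values must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError("spacing must be three positive lengths (mm)")
        if not np.all(np.isfinite(self.values)):
            raise InputError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def lower_corner(self) -> np.ndarray:
        """Physical coordinate of the outer corner of voxel (0,0,0), mm."""
        return np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)

    @property
    def upper_corner(self) -> np.ndarray:
        return self.lower_corner + np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_physical(self, index) -> np.ndarray:
        """Centre coordinate(s) of voxel index/indices, mm."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry and different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise InputError("replacement values must match the grid shape")
        return VoxelGrid(values, self.spacing, self.origin)


@dataclass
class LabelGrid:
    """One boolean mask per structure, geometrically congruent with a VoxelGrid."""

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GeometryError("structure masks have inconsistent shapes")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        if not self.masks:
            raise GeometryError("LabelGrid has no structures")
        return next(iter(self.masks.values())).shape

    def structure(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise GeometryError(f"no structure named {name!r}") from None

    def labels_at(self, index) -> set[str]:
        i, j, k = index
        return {name for name, m in self.masks.items() if m[i, j, k]}

    def congruent_with(self, grid: VoxelGrid) -> bool:
        return (
            self.shape == grid.shape
            and np.allclose(self.spacing, grid.spacing)
            and np.allclose(self.origin, grid.origin)
        )


@dataclass(frozen=True)
class FieldMask:
    """Conformal aperture in the beam's-eye plane at the isocenter.

    Pixel (i, j) covers lateral coordinate ``s0 + i*pitch_s`` (mm, relative to
    the isocenter along the beam's lateral axis) and longitudinal coordinate
    ``z0 + j*pitch_z`` (mm, relative to the isocenter z).
    """

    mask: np.ndarray
    pitch: tuple[float, float]  # (lateral, z) mm
    s0: float
    z0: float
    dilation_voxels: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise InputError("field mask must be 2-D")

    @property
    def area_pixels(self) -> int:
        return int(self.mask.sum())

    def contains(self, s, z) -> np.ndarray:
        """Vectorized in-aperture test for lateral/z coordinates (mm)."""
        s, z = np.broadcast_arrays(np.asarray(s, dtype=float), np.asarray(z, dtype=float))
        ps, pz = self.pitch
        i = np.floor((s - (self.s0 - 0.5 * ps)) / ps).astype(int)
        j = np.floor((z - (self.z0 - 0.5 * pz)) / pz).astype(int)
        ok = (i >= 0) & (i < self.mask.shape[0]) & (j >= 0) & (j < self.mask.shape[1])
        out = np.zeros(s.shape, dtype=bool)
        out[ok] = self.mask[i[ok], j[ok]]
        return out


def beam_axes(gantry_angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(propagation direction, lateral axis) unit vectors of a coplanar beam."""
    t = np.deg2rad(gantry_angle_deg)
    direction = np.array([np.sin(t), -np.cos(t), 0.0])
    lateral = np.array([np.cos(t), np.sin(t), 0.0])
    return direction, lateral


def resample_double_xy(grid: VoxelGrid) -> VoxelGrid:
    """Double the in-plane voxel dimensions by 2x2 averaging; z unchanged.

    Odd trailing rows/columns are truncated with a warning.
    """
    nx, ny, nz = grid.shape
    if nx % 2 or ny % 2:
        warnings.warn("odd in-plane extent: trailing row/column truncated", stacklevel=2)
    nx2, ny2 = nx // 2, ny // 2
    if nx2 == 0 or ny2 == 0:
        raise GeometryError("grid too small to downsample in-plane")
    v = grid.values[: 2 * nx2, : 2 * ny2, :]
    merged = v.reshape(nx2, 2, ny2, 2, nz).mean(axis=(1, 3))
    sx, sy, sz = grid.spacing
    origin = (grid.origin[0] + sx / 2.0, grid.origin[1] + sy / 2.0, grid.origin[2])
    return VoxelGrid(merged, (2 * sx, 2 * sy, sz), origin)


def resample_labels_double_xy(labels: LabelGrid) -> LabelGrid:
    """Companion labelmap downsampling by 2x2 majority vote, ties -> inside."""
    nx, ny, nz = labels.shape
    nx2, ny2 = nx // 2, ny // 2
    out = {}
    for name, m in labels.masks.items():
        counts = (
            m[: 2 * nx2, : 2 * ny2, :]
            .astype(np.int8)
            .reshape(nx2, 2, ny2, 2, nz)
            .sum(axis=(1, 3))
        )
        out[name] = counts >= 2
    sx, sy, sz = labels.spacing
    origin = (labels.origin[0] + sx / 2.0, labels.origin[1] + sy / 2.0, labels.origin[2])
    return LabelGrid(out, (2 * sx, 2 * sy, sz), origin)


def project_target(
    structure_mask: np.ndarray,
    grid: VoxelGrid,
    gantry_angle_deg: float,
    isocenter: Sequence[float],
    pitch: tuple[float, float] | None = None,
    margin_pixels: int = 3,
) -> FieldMask:
    """Binary shadow of a structure along the beam axis (beam's-eye view).

    Every structure voxel's centre projects inside the returned (undilated)
    mask by construction; the one-or-two voxel dilation applied afterwards
    absorbs footprint edge effects.
    """
    idx = np.argwhere(np.asarray(structure_mask, dtype=bool))
    if idx.size == 0:
        raise GeometryError("cannot project an empty structure")
    centers = grid.index_to_physical(idx)
    _, lateral = beam_axes(gantry_angle_deg)
    rel = centers - np.asarray(isocenter, dtype=float)
    s = rel @ lateral
    z = rel[:, 2]
    if pitch is None:
        pitch = (min(grid.spacing[0], grid.spacing[1]), grid.spacing[2])
    ps, pz = pitch
    s0 = float(s.min()) - margin_pixels * ps
    z0 = float(z.min()) - margin_pixels * pz
    ns = int(np.floor((s.max() - s0) / ps)) + 1 + margin_pixels
    nz = int(np.floor((z.max() - z0) / pz)) + 1 + margin_pixels
    mask = np.zeros((ns, nz), dtype=bool)
    i = np.floor((s - (s0 - 0.5 * ps)) / ps).astype(int)
    j = np.floor((z - (z0 - 0.5 * pz)) / pz).astype(int)
    mask[i, j] = True
    return FieldMask(mask, (ps, pz), s0, z0)


def dilate_mask(mask: FieldMask, radius_voxels: int) -> FieldMask:
    """Morphological dilation with a square structuring element.

    The usual conformal margin is one or two voxels; other radii work but warn.
    Radius 0 is the identity.
    """
    if radius_voxels not in (1, 2):
        warnings.warn(
            f"dilation radius {radius_voxels} outside the usual 1-2 voxel margin",
            stacklevel=2,
        )
    if radius_voxels == 0:
        return replace(mask, dilation_voxels=mask.dilation_voxels)
    if radius_voxels < 0:
        raise InputError("dilation radius must be non-negative")
    size = 2 * radius_voxels + 1
    dilated = ndimage.binary_dilation(mask.mask, structure=np.ones((size, size), bool))
    return FieldMask(
        dilated, mask.pitch, mask.s0, mask.z0, mask.dilation_voxels + radius_voxels
    )


def arrange_beams(
    angles_deg: Sequence[float],
    *,
    target_mask: np.ndarray,
    grid: VoxelGrid,
    isocenter: Sequence[float],
    entrance_peak_dose: float,
    weights: Sequence[float] | None = None,
    dilation_voxels: int = 1,
    aperture_pitch: tuple[float, float] | None = None,
    **lattice_kwargs,
):
    """One conformal BeamSpec per gantry angle (cross-firing arrangement).

    ``lattice_kwargs`` are forwarded to :class:`mrteud.microdose.BeamSpec`
    (peak width, centre-to-centre distance, valley fraction, effective mu,
    penumbra, scatter fraction).  Per-beam ``weights`` scale the shared
    ``entrance_peak_dose``.
    """
    from .microdose import BeamSpec  # local import: BeamSpec lives with the engine

    if len(angles_deg) == 0:
        raise InputError("empty beam-angle list")
    if weights is None:
        weights = [1.0] * len(angles_deg)
    if len(weights) != len(angles_deg):
        raise InputError("weights must match the number of angles")
    if any(w <= 0 for w in weights):
        raise InputError("beam weights must be positive")
    if len({float(a) % 360.0 for a in angles_deg}) < len(angles_deg):
        warnings.warn("duplicate gantry angles: field will be double-weighted", stacklevel=2)
    beams = []
    for angle, w in zip(angles_deg, weights):
        aperture = dilate_mask(
            project_target(target_mask, grid, angle, isocenter, pitch=aperture_pitch),
            dilation_voxels,
        )
        beams.append(
            BeamSpec(
                gantry_angle=float(angle),
                entrance_peak_dose=float(entrance_peak_dose) * float(w),
                isocenter=tuple(float(c) for c in isocenter),
                field_mask=aperture,
                **lattice_kwargs,
            )
        )
    return beams
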