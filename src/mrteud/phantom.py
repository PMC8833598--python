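"""Synthetic voxel phantoms: a body-like density grid with target and OARs.

Emulates the geometry the evaluation pipeline needs without any patient
data: a water-equivalent body (cylinder or slab) surrounded by near-air,
a spherical target (PTV) and labelled spherical/shell organs at risk,
optionally a low-density lung-like compartment.  The default phantom
includes an OAR overlapping the PTV to exercise tissue-parameter priority,
mirroring the clinically common situation of organs abutting or overlapping
the target volume.

Generation is deterministic; the seed only drives optional density noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .geometry import LabelGrid, VoxelGrid

__all__ = [
    "SphereSpec",
    "ShellSpec",
    "BoxSpec",
    "PhantomSpec",
    "generate_phantom",
    "default_phantom_spec",
]


@dataclass(frozen=True)
class SphereSpec:
    """Labelled sphere: centre (mm, physical coordinates) and diameter (mm)."""

    label: str
    center_mm: tuple[float, float, float]
    diameter_mm: float

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def bounding_radius_mm(self) -> float:
        return self.radius_mm

    def mask(self, centers: np.ndarray) -> np.ndarray:
        r2 = np.sum((centers - np.asarray(self.center_mm)) ** 2, axis=-1)
        return r2 <= self.radius_mm**2


@dataclass(frozen=True)
class ShellSpec:
    """Labelled spherical shell (e.g. a hollow organ wall)."""

    label: str
    center_mm: tuple[float, float, float]
    inner_diameter_mm: float
    outer_diameter_mm: float

    @property
    def bounding_radius_mm(self) -> float:
        return self.outer_diameter_mm / 2.0

    def mask(self, centers: np.ndarray) -> np.ndarray:
        r2 = np.sum((centers - np.asarray(self.center_mm)) ** 2, axis=-1)
        return ((self.inner_diameter_mm / 2.0) ** 2 < r2) & (
            r2 <= (self.outer_diameter_mm / 2.0) ** 2
        )


@dataclass(frozen=True)
class BoxSpec:
    """Axis-aligned box region, used for low-density compartments."""

    label: str
    lower_mm: tuple[float, float, float]
    upper_mm: tuple[float, float, float]
    density: float = 0.26  # lung-like

    def mask(self, centers: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lower_mm)
        hi = np.asarray(self.upper_mm)
        return np.all((centers >= lo) & (centers <= hi), axis=-1)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic phantom.

    The grid is centred on the physical origin; structure positions are in mm
    relative to that centre.  ``body_kind`` is ``"cylinder"`` (axis z,
    ``body_radius_mm``) or ``"slab"`` (whole grid).
    """

    shape: tuple[int, int, int] = (40, 40, 10)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_kind: str = "cylinder"
    body_radius_mm: float = 36.0
    body_density: float = 1.0
    outside_density: float = 0.001
    target: SphereSpec = SphereSpec("PTV", (0.0, 10.0, 0.0), 16.0)
    oars: tuple = ()
    lung: BoxSpec | None = None
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.body_kind not in ("cylinder", "slab"):
            raise ConfigError(f"unknown body kind {self.body_kind!r}")
        if any(n < 1 for n in self.shape) or any(s <= 0 for s in self.spacing_mm):
            raise ConfigError("invalid phantom grid shape or spacing")
        if not 0 < self.outside_density < self.body_density:
            raise ConfigError("need 0 < outside density < body density")
        half_extent = 0.5 * np.asarray(self.shape) * np.asarray(self.spacing_mm)
        for s in (self.target, *self.oars):
            c = np.asarray(s.center_mm)
            rb = s.bounding_radius_mm
            if self.body_kind == "cylinder":
                inside = np.hypot(c[0], c[1]) + rb <= self.body_radius_mm and (
                    abs(c[2]) + rb <= half_extent[2]
                )
            else:
                inside = np.all(np.abs(c) + rb <= half_extent)
            if not inside:
                raise ConfigError(f"structure {s.label!r} extends outside the body")
        labels = [self.target.label] + [o.label for o in self.oars]
        if len(set(labels)) != len(labels):
            raise ConfigError("structure labels must be unique")


def default_phantom_spec() -> PhantomSpec:
    """Small head-like phantom with a PTV-overlapping OAR and a separate OAR."""
    return PhantomSpec(
        oars=(
            SphereSpec("brain_stem", (0.0, 0.0, 0.0), 10.0),  # overlaps the PTV
            SphereSpec("cochlea", (14.0, 6.0, 0.0), 6.0),
        )
    )


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[VoxelGrid, LabelGrid]:
    """Rasterize a phantom spec to a density grid plus structure labelmaps.

    Voxel-centre rasterization; deterministic for a given spec and seed.
    """
    shape = tuple(int(n) for n in spec.shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    ii = np.indices(shape, dtype=float)
    centers = np.stack(
        [origin[a] + ii[a] * spacing[a] for a in range(3)], axis=-1
    )  # (nx, ny, nz, 3)

    if spec.body_kind == "cylinder":
        body = np.hypot(centers[..., 0], centers[..., 1]) <= spec.body_radius_mm
    else:
        body = np.ones(shape, dtype=bool)
    density = np.where(body, spec.body_density, spec.outside_density)
    if spec.lung is not None:
        density = np.where(spec.lung.mask(centers) & body, spec.lung.density, density)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        density = np.clip(
            density * (1.0 + spec.noise_sigma * rng.standard_normal(shape)),
            spec.outside_density / 10.0,
            None,
        )

    masks = {spec.target.label: spec.target.mask(centers)}
    for oar in spec.oars:
        masks[oar.label] = oar.mask(centers)
    if spec.lung is not None:
        masks[spec.lung.label] = spec.lung.mask(centers) & body

    grid = VoxelGrid(density, spacing, origin)
    labels = LabelGrid(masks, spacing, origin)
    return grid, labels
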