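"""Declarative plan configuration (YAML/JSON).

One file fully describes a plan: the phantom (or imported grids), the beam
set, tissue table, structure priority, constraints and the normalization
prescription.  See ``PlanConfig`` for the schema; unknown keys are rejected
so typos fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError
from .evaluation import ConstraintSpec, load_constraint_table
from .geometry import LabelGrid, VoxelGrid, arrange_beams
from .gridio import packaged_data_path, read_grid, read_labels
from .histogram import DEFAULT_N_BINS
from .phantom import BoxSpec, PhantomSpec, ShellSpec, SphereSpec, generate_phantom
from .radiobiology import TissueParams, load_tissue_table

__all__ = ["BeamSetConfig", "SamplingConfig", "PlanConfig", "load_plan_config"]


def _take(mapping: Mapping, allowed: set[str], context: str) -> dict:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")
    return dict(mapping)


@dataclass(frozen=True)
class BeamSetConfig:
    """Shared lattice parameters plus gantry angles and weights."""

    angles_deg: tuple[float, ...]
    entrance_peak_dose_gy: float = 100.0
    weights: tuple[float, ...] | None = None
    peak_width_um: float = 50.0
    center_to_center_um: float = 400.0
    valley_fraction: float = 0.05
    effective_mu_cm: float = 0.169
    penumbra_sigma_um: float = 0.0
    scatter_fraction: float = 0.0
    dilation_voxels: int = 1

    @classmethod
    def from_dict(cls, d: Mapping) -> "BeamSetConfig":
        d = _take(d, {f.name for f in cls.__dataclass_fields__.values()} | {"angles_deg"}, "beams")
        if "angles_deg" not in d:
            raise ConfigError("beams.angles_deg is required")
        d["angles_deg"] = tuple(float(a) for a in d["angles_deg"])
        if d.get("weights") is not None:
            d["weights"] = tuple(float(w) for w in d["weights"])
        return cls(**d)


@dataclass(frozen=True)
class SamplingConfig:
    """Subvoxel sampling: isotropic pitch with an optional z override.

    The microbeam lattice of coplanar beams is invariant along z, so the
    default uses a single z subdivision per voxel; set ``z_subdivisions``
    to 0/None to sample isotropically at ``pitch_um`` along z as well.
    """

    pitch_um: float = 25.0
    z_subdivisions: int | None = 1

    @classmethod
    def from_dict(cls, d: Mapping) -> "SamplingConfig":
        return cls(**_take(d, {"pitch_um", "z_subdivisions"}, "sampling"))

    def subdivisions_for(self, spacing_mm: Sequence[float]) -> tuple[int, int, int]:
        subs = [max(1, int(round(sp * 1000.0 / self.pitch_um))) for sp in spacing_mm]
        if self.z_subdivisions:
            subs[2] = int(self.z_subdivisions)
        return tuple(subs)


def _structure_from_dict(d: Mapping):
    d = dict(d)
    kind = d.pop("kind", "sphere")
    if kind == "sphere":
        return SphereSpec(d["label"], tuple(d["center_mm"]), float(d["diameter_mm"]))
    if kind == "shell":
        return ShellSpec(
            d["label"],
            tuple(d["center_mm"]),
            float(d["inner_diameter_mm"]),
            float(d["outer_diameter_mm"]),
        )
    raise ConfigError(f"unknown structure kind {kind!r}")


def _phantom_from_dict(d: Mapping) -> PhantomSpec:
    d = _take(
        d,
        {
            "shape",
            "spacing_mm",
            "body_kind",
            "body_radius_mm",
            "body_density",
            "outside_density",
            "target",
            "oars",
            "lung",
            "noise_sigma",
        },
        "phantom",
    )
    if "target" in d:
        d["target"] = _structure_from_dict(d["target"])
    if "oars" in d:
        d["oars"] = tuple(_structure_from_dict(o) for o in d["oars"])
    if d.get("lung") is not None:
        lung = dict(d["lung"])
        d["lung"] = BoxSpec(
            lung.get("label", "lung"),
            tuple(lung["lower_mm"]),
            tuple(lung["upper_mm"]),
            float(lung.get("density", 0.26)),
        )
    if "shape" in d:
        d["shape"] = tuple(int(n) for n in d["shape"])
    if "spacing_mm" in d:
        d["spacing_mm"] = tuple(float(s) for s in d["spacing_mm"])
    return PhantomSpec(**d)


@dataclass(frozen=True)
class PlanConfig:
    """Everything needed to simulate and evaluate one plan."""

    beams: BeamSetConfig
    phantom: PhantomSpec | None = None
    density_path: str | None = None
    labels_dir: str | None = None
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    tissue_table: str | None = None
    priority: tuple[str, ...] | None = None
    constraints_path: str | None = None
    target: str = "PTV"
    reference_d98_gy: float | None = None
    n_bins: int = DEFAULT_N_BINS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phantom is None and (self.density_path is None or self.labels_dir is None):
            raise ConfigError("config needs either a phantom block or grid paths")

    def load_grids(self) -> tuple[VoxelGrid, LabelGrid]:
        if self.phantom is not None:
            return generate_phantom(self.phantom, seed=self.seed)
        return read_grid(self.density_path), read_labels(self.labels_dir)

    def registry(self) -> dict[str, TissueParams]:
        path = self.tissue_table or packaged_data_path("tissue_params.csv")
        return load_tissue_table(path)

    def constraints(self) -> list[ConstraintSpec]:
        if self.constraints_path is None:
            return []
        return load_constraint_table(self.constraints_path)

    def build_beams(self, density: VoxelGrid, labels: LabelGrid):
        target_mask = labels.structure(self.target)
        import numpy as np

        idx = np.argwhere(target_mask)
        isocenter = density.index_to_physical(idx.mean(axis=0))
        b = self.beams
        return arrange_beams(
            b.angles_deg,
            target_mask=target_mask,
            grid=density,
            isocenter=isocenter,
            entrance_peak_dose=b.entrance_peak_dose_gy,
            weights=b.weights,
            dilation_voxels=b.dilation_voxels,
            peak_width_um=b.peak_width_um,
            center_to_center_um=b.center_to_center_um,
            valley_fraction=b.valley_fraction,
            effective_mu_cm=b.effective_mu_cm,
            penumbra_sigma_um=b.penumbra_sigma_um,
            scatter_fraction=b.scatter_fraction,
        )


def load_plan_config(path) -> PlanConfig:
    """Parse a YAML or JSON plan configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except Exception as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    raw = _take(
        raw,
        {
            "phantom",
            "grids",
            "beams",
            "sampling",
            "tissue_table",
            "priority",
            "constraints",
            "target",
            "reference_d98_gy",
            "n_bins",
            "seed",
        },
        "config",
    )
    if "beams" not in raw:
        raise ConfigError("config needs a beams block")
    kwargs: dict = {"beams": BeamSetConfig.from_dict(raw["beams"])}
    if "phantom" in raw:
        kwargs["phantom"] = _phantom_from_dict(raw["phantom"])
    if "grids" in raw:
        grids = _take(raw["grids"], {"density", "labels_dir"}, "grids")
        kwargs["density_path"] = grids.get("density")
        kwargs["labels_dir"] = grids.get("labels_dir")
    if "sampling" in raw:
        kwargs["sampling"] = SamplingConfig.from_dict(raw["sampling"])
    for key_src, key_dst in [
        ("tissue_table", "tissue_table"),
        ("constraints", "constraints_path"),
        ("target", "target"),
        ("reference_d98_gy", "reference_d98_gy"),
        ("n_bins", "n_bins"),
        ("seed", "seed"),
    ]:
        if key_src in raw and raw[key_src] is not None:
            kwargs[key_dst] = raw[key_src]
    if raw.get("priority") is not None:
        kwargs["priority"] = tuple(str(p) for p in raw["priority"])
    # resolve relative paths against the config file location
    for key in ("tissue_table", "constraints_path", "density_path", "labels_dir"):
        if kwargs.get(key):
            p = Path(kwargs[key])
            if not p.is_absolute():
                kwargs[key] = str(path.parent / p)
    return PlanConfig(**kwargs)
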