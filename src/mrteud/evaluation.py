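"""Plan evaluation: EUD/EQD2 maps, DVHs, dose metrics, D98% normalization
and organ-at-risk constraint reports.

Dose-metric conventions
-----------------------
``D_x%`` is the minimum dose received by the hottest x% of the structure
volume (so D2% is near-maximum and D98% near-minimum), evaluated with linear
interpolation on the cumulative hottest-volume curve; ``D_Vcc`` is the same
for an absolute hottest volume in cm^3 with partial-voxel interpolation;
``V_dGy`` is the percentage of the structure volume at or above a dose
(whole-voxel counting); ``V_x%`` is read as the dose received by x% of the
volume (an alias of D_x%, the common constraint-table shorthand).

All comparisons against constraint tables happen on the EQD2 scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError, ConvergenceError, GeometryError, InputError
from .geometry import LabelGrid, VoxelGrid
from .histogram import DEFAULT_N_BINS, build_histogram
from .microdose import BeamSpec, sample_subvoxel_doses
from .radiobiology import (
    DEFAULT_NORMAL_TISSUE,
    TissueParams,
    eqd2,
    eqd2_of_single_fraction_eud,
    eud_batch,
    resolve_tissue_params,
)

__all__ = [
    "DVHCurve",
    "Metric",
    "ConstraintSpec",
    "ConstraintReport",
    "resolve_params_arrays",
    "collect_histograms",
    "eud_map",
    "eqd2_map",
    "dvh",
    "dose_metric",
    "normalize_to_reference_d98",
    "NormalizationResult",
    "evaluate_constraints",
    "constraint_report",
    "load_constraint_table",
]


# ---------------------------------------------------------------------------
# DVH


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve: % of structure volume receiving >= dose."""

    dose: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        v = np.asarray(self.volume_pct, dtype=float)
        if d.shape != v.shape or d.ndim != 1 or d.size < 2:
            raise InputError("DVH needs matching 1-D dose and volume arrays")
        if d[0] != 0.0 or v[0] != 100.0:
            raise InputError("DVH must start at (0 Gy, 100%)")
        if np.any(np.diff(d) < 0) or np.any(np.diff(v) > 0):
            raise InputError("DVH must be non-increasing over non-decreasing dose")
        if v[-1] != 0.0:
            raise InputError("DVH must reach 0% beyond the maximum dose")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "volume_pct", v)

    def volume_pct_at(self, dose) -> np.ndarray:
        """Step-wise % of volume receiving at least ``dose``.

        Between nodes the curve steps down at the next node dose (a voxel at
        dose D contributes to all query doses <= D), so the value for a query
        in (u_i, u_{i+1}] is the node value at u_{i+1}.
        """
        d = np.asarray(dose, dtype=float)
        idx = np.searchsorted(self.dose, d, side="left")
        out = self.volume_pct[np.clip(idx, 0, self.dose.size - 1)]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.dose, "volume_pct": self.volume_pct})


def dvh(dose_map: VoxelGrid | np.ndarray, structure_mask: np.ndarray) -> DVHCurve:
    """Cumulative DVH of a structure (equal voxel volumes within one grid)."""
    values = dose_map.values if isinstance(dose_map, VoxelGrid) else np.asarray(dose_map)
    mask = np.asarray(structure_mask, dtype=bool)
    doses = values[mask]
    if doses.size == 0:
        raise GeometryError("empty structure in DVH computation")
    u = np.unique(doses)
    n = doses.size
    pct = 100.0 * (n - np.searchsorted(np.sort(doses), u, side="left")) / n
    dose_axis = [0.0, *u.tolist()]
    vol_axis = [100.0, *pct.tolist()]
    eps = max(abs(u[-1]) * 1e-12, 1e-12)
    dose_axis.append(u[-1] + eps)
    vol_axis.append(0.0)
    if dose_axis[1] == 0.0:  # avoid a duplicate 0 Gy node
        dose_axis.pop(0)
        vol_axis.pop(1)
    return DVHCurve(np.asarray(dose_axis), np.asarray(vol_axis))


# ---------------------------------------------------------------------------
# Dose metrics


_METRIC_PATTERNS = [
    (re.compile(r"^D_?max$", re.I), "dmax"),
    (re.compile(r"^D_?mean$", re.I), "dmean"),
    (re.compile(r"^D_?([\d.]+)\s*%$", re.I), "dose_at_pct"),
    (re.compile(r"^D_?([\d.]+)\s*(?:cc|cm3|cm\^?3)$", re.I), "dose_at_cc"),
    (re.compile(r"^V_?([\d.]+)\s*Gy$", re.I), "vol_pct_at_dose"),
    (re.compile(r"^V_?([\d.]+)\s*%$", re.I), "dose_at_pct"),  # V_x% constraint shorthand
]


@dataclass(frozen=True)
class Metric:
    """One dose metric: kind plus its query value (percent, cm^3 or Gy)."""

    kind: str
    value: float | None = None

    _KINDS = ("dmax", "dmean", "dose_at_pct", "dose_at_cc", "vol_pct_at_dose")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InputError(f"unknown metric kind {self.kind!r}")
        if self.kind in ("dmax", "dmean"):
            if self.value is not None:
                raise InputError(f"{self.kind} takes no query value")
        elif self.value is None or self.value <= 0:
            raise InputError(f"{self.kind} needs a positive query value")
        if self.kind == "dose_at_pct" and not 0 < self.value <= 100:
            raise InputError("volume percentage must be in (0, 100]")

    @classmethod
    def parse(cls, text: str) -> "Metric":
        text = text.strip()
        for pattern, kind in _METRIC_PATTERNS:
            m = pattern.match(text)
            if m:
                value = float(m.group(1)) if m.groups() else None
                return cls(kind, value)
        raise ConfigError(f"cannot parse metric {text!r}")

    def __str__(self) -> str:
        if self.kind == "dmax":
            return "Dmax"
        if self.kind == "dmean":
            return "Dmean"
        if self.kind == "dose_at_pct":
            return f"D{self.value:g}%"
        if self.kind == "dose_at_cc":
            return f"D{self.value:g}cc"
        return f"V{self.value:g}Gy"

    @property
    def unit(self) -> str:
        return "%" if self.kind == "vol_pct_at_dose" else "Gy"


def _dose_at_cumulative_volume(doses_desc: np.ndarray, volumes: np.ndarray, v: float) -> float:
    """Linear interpolation of dose vs cumulative hottest volume.

    Nodes are (cumulative volume after the k hottest voxels, dose of the k-th
    hottest voxel); below the first node the maximum dose is returned.
    """
    cum = np.cumsum(volumes)
    return float(np.interp(v, cum, doses_desc))


def dose_metric(
    dose_map: VoxelGrid | np.ndarray,
    structure_mask: np.ndarray,
    metric: Metric | str,
    voxel_volume_cm3: float | None = None,
) -> float:
    """Evaluate one dose metric over a structure.

    ``voxel_volume_cm3`` is required for absolute-volume metrics; it is taken
    from the grid when a :class:`VoxelGrid` is passed.
    """
    if isinstance(metric, str):
        metric = Metric.parse(metric)
    if isinstance(dose_map, VoxelGrid):
        values = dose_map.values
        if voxel_volume_cm3 is None:
            voxel_volume_cm3 = dose_map.voxel_volume_cm3
    else:
        values = np.asarray(dose_map, dtype=float)
    mask = np.asarray(structure_mask, dtype=bool)
    doses = values[mask]
    if doses.size == 0:
        raise GeometryError("empty structure in dose metric")

    if metric.kind == "dmax":
        return float(doses.max())
    if metric.kind == "dmean":
        return float(doses.mean())
    if metric.kind == "vol_pct_at_dose":
        return float(100.0 * np.count_nonzero(doses >= metric.value) / doses.size)

    doses_desc = np.sort(doses)[::-1]
    if metric.kind == "dose_at_pct":
        volumes = np.full(doses.size, 1.0 / doses.size)  # fractional volumes
        return _dose_at_cumulative_volume(doses_desc, volumes, metric.value / 100.0)
    # dose_at_cc
    if voxel_volume_cm3 is None:
        raise InputError("absolute-volume metric needs the voxel volume")
    total = doses.size * voxel_volume_cm3
    if metric.value > total:
        raise InputError(
            f"requested volume {metric.value} cm^3 exceeds structure volume {total:.3f} cm^3"
        )
    volumes = np.full(doses.size, voxel_volume_cm3)
    return _dose_at_cumulative_volume(doses_desc, volumes, metric.value)


# ---------------------------------------------------------------------------
# Voxel-wise EUD / EQD2 maps


def resolve_params_arrays(
    labels: LabelGrid,
    registry: Mapping[str, TissueParams],
    priority: Sequence[str] | None = None,
    default: TissueParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (alpha, beta) arrays from labelmaps with priority overlap rule."""
    if len(registry) == 0:
        raise ConfigError("empty tissue-parameter registry")
    if default is None:
        default = registry.get("default", DEFAULT_NORMAL_TISSUE)
    shape = labels.shape
    alpha = np.full(shape, default.alpha)
    beta = np.full(shape, default.beta)
    order = list(priority) if priority is not None else []
    order += [k for k in labels.masks if k not in order]
    # lowest precedence first, so higher-priority labels overwrite
    for name in reversed(order):
        if name not in labels.masks or name not in registry:
            continue
        m = labels.masks[name]
        alpha[m] = registry[name].alpha
        beta[m] = registry[name].beta
    return alpha, beta


def collect_histograms(
    voxel_indices: np.ndarray,
    block_provider: Callable[[tuple[int, int, int]], object],
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel padded (weights, doses) arrays of shape (n_voxels, n_bins)."""
    n_vox = len(voxel_indices)
    W = np.zeros((n_vox, n_bins))
    D = np.zeros((n_vox, n_bins))
    for row, idx in enumerate(voxel_indices):
        hist = build_histogram(block_provider(tuple(idx)), n_bins=n_bins)
        W[row, : hist.n_bins] = hist.bin_weights
        D[row, : hist.n_bins] = hist.bin_doses
    return W, D


def eud_map(
    density: VoxelGrid,
    labels: LabelGrid,
    beams: Sequence[BeamSpec],
    registry: Mapping[str, TissueParams],
    priority: Sequence[str] | None = None,
    *,
    region: np.ndarray | None = None,
    subdivisions: tuple[int, int, int] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    block_provider: Callable | None = None,
) -> VoxelGrid:
    """Voxel-wise EUD map (Gy): subvoxel sampling -> histogram -> EUD.

    ``region`` restricts the computation to a boolean voxel mask (voxels
    outside keep EUD 0, appropriate when they receive no dose); any
    ``block_provider(index) -> SubvoxelBlock`` may replace the built-in
    analytic engine.
    """
    if not labels.congruent_with(density):
        raise GeometryError("labelmaps not congruent with the density grid")
    if block_provider is None:
        def block_provider(idx):
            return sample_subvoxel_doses(idx, beams, density, subdivisions=subdivisions)

    if region is None:
        region = np.ones(density.shape, dtype=bool)
    indices = np.argwhere(region)
    W, D = collect_histograms(indices, block_provider, n_bins=n_bins)
    alpha3d, beta3d = resolve_params_arrays(labels, registry, priority)
    a = alpha3d[indices[:, 0], indices[:, 1], indices[:, 2]]
    b = beta3d[indices[:, 0], indices[:, 1], indices[:, 2]]
    out = np.zeros(density.shape)
    out[indices[:, 0], indices[:, 1], indices[:, 2]] = eud_batch(W, D, a, b)
    return density.like(out)


def eqd2_map(
    dose_map: VoxelGrid,
    labels: LabelGrid,
    registry: Mapping[str, TissueParams],
    priority: Sequence[str] | None = None,
    *,
    single_fraction: bool = False,
    n_fractions: int | None = None,
    fraction_dose: float | None = None,
) -> VoxelGrid:
    """Voxel-wise EQD2 conversion with per-voxel alpha/beta.

    MRT EUD maps use ``single_fraction=True`` (the whole voxel EUD is one
    fraction).  Clinical maps need either ``n_fractions`` (voxel fraction dose
    = voxel dose / n) or an explicit uniform ``fraction_dose``.
    """
    alpha3d, beta3d = resolve_params_arrays(labels, registry, priority)
    ab = alpha3d / beta3d
    values = dose_map.values
    if np.any(values < 0):
        raise InputError("dose map must be non-negative")
    if single_fraction:
        out = eqd2_of_single_fraction_eud(values, ab)
    else:
        if fraction_dose is not None:
            if fraction_dose <= 0:
                raise InputError("fraction dose must be positive")
            d = np.full_like(values, float(fraction_dose))
        elif n_fractions is not None:
            if n_fractions < 1:
                raise InputError("need at least one fraction")
            d = values / float(n_fractions)
        else:
            raise InputError("clinical EQD2 map needs a fraction scheme")
        out = np.where(values > 0, values * (d + ab) / (2.0 + ab), 0.0)
    return dose_map.like(out)


# ---------------------------------------------------------------------------
# D98% normalization


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of matching the PTV D98% of the EQD2(EUD) map to a reference."""

    factor: float
    achieved_d98: float
    reference_d98: float
    beams: tuple[BeamSpec, ...]


def normalize_to_reference_d98(
    beams: Sequence[BeamSpec],
    density: VoxelGrid,
    labels: LabelGrid,
    registry: Mapping[str, TissueParams],
    reference_d98: float,
    target: str = "PTV",
    priority: Sequence[str] | None = None,
    *,
    subdivisions: tuple[int, int, int] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    block_provider: Callable | None = None,
    rel_tol: float = 1e-3,
) -> NormalizationResult:
    """Scale all beam weights by one factor so the target D98% of the
    EQD2(EUD) map matches ``reference_d98`` within ``rel_tol`` (default 0.1%).

    The engine is linear in the beam weights, so subvoxel doses (and hence
    histogram bin doses) scale exactly with the factor; the histograms are
    sampled once and the scalar solve (Brent's method on a monotone function)
    reuses them.
    """
    if reference_d98 <= 0:
        raise InputError("reference D98% must be positive")
    mask = labels.structure(target)
    indices = np.argwhere(mask)
    if indices.size == 0:
        raise GeometryError(f"target structure {target!r} is empty")
    if block_provider is None:
        def block_provider(idx):
            return sample_subvoxel_doses(idx, beams, density, subdivisions=subdivisions)
    W, D = collect_histograms(indices, block_provider, n_bins=n_bins)
    alpha3d, beta3d = resolve_params_arrays(labels, registry, priority)
    a = alpha3d[indices[:, 0], indices[:, 1], indices[:, 2]]
    b = beta3d[indices[:, 0], indices[:, 1], indices[:, 2]]

    def d98_of(k: float) -> float:
        eud = eud_batch(W, k * D, a, b)
        eqd = eqd2_of_single_fraction_eud(eud, a / b)
        desc = np.sort(eqd)[::-1]
        return _dose_at_cumulative_volume(desc, np.full(desc.size, 1.0 / desc.size), 0.98)

    if d98_of(1.0) == 0.0:
        raise ConvergenceError("target receives no dose; cannot normalize")

    lo, hi = 1.0, 1.0
    for _ in range(60):
        if d98_of(lo) < reference_d98:
            break
        lo /= 4.0
    else:
        raise ConvergenceError("could not bracket the normalization factor from below")
    for _ in range(60):
        if d98_of(hi) > reference_d98:
            break
        hi *= 4.0
    else:
        raise ConvergenceError("could not bracket the normalization factor from above")

    factor = float(
        brentq(lambda k: d98_of(k) - reference_d98, lo, hi, xtol=1e-12, rtol=1e-10)
    )
    achieved = d98_of(factor)
    if abs(achieved - reference_d98) > rel_tol * reference_d98:
        raise ConvergenceError(
            f"normalization reached D98% = {achieved:.4f} Gy, "
            f"outside {rel_tol:.1%} of the reference {reference_d98:.4f} Gy"
        )
    return NormalizationResult(
        factor=factor,
        achieved_d98=achieved,
        reference_d98=float(reference_d98),
        beams=tuple(b_.scaled(factor) for b_ in beams),
    )


# ---------------------------------------------------------------------------
# Constraint tables


@dataclass(frozen=True)
class ConstraintSpec:
    """One organ-at-risk constraint on the EQD2 scale."""

    structure: str
    metric: Metric
    threshold: float
    comparator: str = "<"
    plan: str | None = None

    def __post_init__(self) -> None:
        if self.comparator not in ("<", "<="):
            raise ConfigError(f"unsupported comparator {self.comparator!r}")
        if self.threshold <= 0:
            raise ConfigError("constraint threshold must be positive")

    def passes(self, achieved: float) -> bool:
        return achieved < self.threshold if self.comparator == "<" else achieved <= self.threshold

    def __str__(self) -> str:
        unit = self.metric.unit if self.metric.kind == "vol_pct_at_dose" else "Gy"
        return f"{self.structure}: {self.metric} {self.comparator} {self.threshold:g} {unit}"


@dataclass(frozen=True)
class ConstraintReport:
    """Pass/fail table of achieved metric values against their constraints."""

    rows: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plan": c.plan,
                    "structure": c.structure,
                    "metric": str(c.metric),
                    "comparator": c.comparator,
                    "threshold": c.threshold,
                    "achieved": achieved,
                    "passed": passed,
                }
                for c, achieved, passed in self.rows
            ]
        )

    @property
    def n_failed(self) -> int:
        return sum(1 for _, _, passed in self.rows if not passed)

    @property
    def all_passed(self) -> bool:
        return self.n_failed == 0


def evaluate_constraints(
    constraints: Sequence[ConstraintSpec],
    achieved: Mapping[tuple[str, str], float],
) -> ConstraintReport:
    """Build a report from pre-computed achieved values.

    ``achieved`` maps ``(structure, metric string)`` to the measured value on
    the EQD2 scale (e.g. from another planning system's printout).
    """
    rows = []
    for c in constraints:
        key = (c.structure, str(c.metric))
        if key not in achieved:
            raise InputError(f"no achieved value for constraint {c}")
        value = float(achieved[key])
        rows.append((c, value, c.passes(value)))
    return ConstraintReport(tuple(rows))


def constraint_report(
    dose_map: VoxelGrid,
    labels: LabelGrid,
    constraints: Sequence[ConstraintSpec],
) -> ConstraintReport:
    """Compute achieved values from an EQD2 dose map and check each constraint."""
    rows = []
    for c in constraints:
        value = dose_metric(dose_map, labels.structure(c.structure), c.metric)
        rows.append((c, value, c.passes(value)))
    return ConstraintReport(tuple(rows))


def load_constraint_table(path) -> list[ConstraintSpec]:
    """Constraints from CSV with columns
    ``structure, metric, threshold[, comparator][, plan]``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ConfigError(f"cannot read constraint table {path!r}: {exc}") from exc
    required = {"structure", "metric", "threshold"}
    if not required.issubset(df.columns):
        raise ConfigError(f"constraint table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ConstraintSpec(
                structure=str(row["structure"]),
                metric=Metric.parse(str(row["metric"])),
                threshold=float(row["threshold"]),
                comparator=str(row.get("comparator", "<")) if not pd.isna(row.get("comparator", np.nan)) else "<",
                plan=str(row["plan"]) if "plan" in df.columns and not pd.isna(row["plan"]) else None,
            )
        )
    return out
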