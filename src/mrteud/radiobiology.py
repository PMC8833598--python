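"""Linear-quadratic radiobiology: survival fractions, EUD and EQD2.

The model
---------
A voxel exposed to a spatially heterogeneous dose is summarized by a dose
histogram ``(w_i, D_i)``: the volume fraction ``w_i`` of the voxel receiving
dose ``D_i``.  Under the linear-quadratic model (LQM) the surviving fraction
of clonogenic cells is

    SF = sum_i w_i * exp(-alpha*D_i - beta*D_i**2)

with tissue-specific ``alpha`` (Gy^-1) and ``beta`` (Gy^-2).  The equivalent
uniform dose (EUD) is the homogeneous dose with the same survival, i.e. the
positive root of ``beta*E**2 + alpha*E + ln(SF) = 0``:

    EUD = -alpha/(2*beta) + sqrt((alpha/(2*beta))**2 - ln(SF)/beta)

Doses are compared on the EQD2 scale (equivalent total dose in 2 Gy
fractions):

    EQD2 = D * (d + alpha/beta) / (2 Gy + alpha/beta)

where ``d`` is the dose per fraction.  A spatially fractionated treatment
delivered in a single session enters with ``d = D = EUD``.

All doses are in Gy; the 2 Gy reference fraction is hard-coded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigError, InputError, SurvivalUnderflowWarning

__all__ = [
    "REFERENCE_FRACTION_DOSE_GY",
    "DEFAULT_NORMAL_TISSUE",
    "TissueParams",
    "DoseHistogram",
    "survival_fraction",
    "log_survival_fraction",
    "eud_from_histogram",
    "eud_batch",
    "eqd2",
    "eqd2_of_single_fraction_eud",
    "resolve_tissue_params",
    "load_tissue_table",
]

#: Reference fraction size of the EQD2 scale, Gy.
REFERENCE_FRACTION_DOSE_GY = 2.0

_CONSISTENCY_RTOL = 1e-9


@dataclass(frozen=True)
class TissueParams:
    """LQM parameters of one structure.

    Any two of ``alpha`` (Gy^-1), ``beta`` (Gy^-2) and ``alpha_beta`` (Gy)
    determine the third; if all three are supplied they must agree to a
    relative 1e-9.
    """

    name: str
    alpha: float | None = None
    beta: float | None = None
    alpha_beta: float | None = None

    def __post_init__(self) -> None:
        a, b, r = self.alpha, self.beta, self.alpha_beta
        known = sum(v is not None for v in (a, b, r))
        if known < 2:
            raise InputError(
                f"TissueParams {self.name!r}: need at least two of alpha, beta, alpha/beta"
            )
        if a is None:
            a = b * r
        elif b is None:
            b = a / r
        elif r is None:
            r = a / b
        else:
            if not math.isclose(r, a / b, rel_tol=_CONSISTENCY_RTOL):
                raise InputError(
                    f"TissueParams {self.name!r}: alpha/beta = {a / b!r} "
                    f"inconsistent with supplied ratio {r!r}"
                )
        if not (a > 0 and b > 0 and r > 0):
            raise InputError(
                f"TissueParams {self.name!r}: alpha, beta and alpha/beta must be positive"
            )
        object.__setattr__(self, "alpha", float(a))
        object.__setattr__(self, "beta", float(b))
        object.__setattr__(self, "alpha_beta", float(r))


#: Default normal-tissue parameters used for unlabeled voxels.
DEFAULT_NORMAL_TISSUE = TissueParams("default", alpha=0.1, beta=0.05)


@dataclass(frozen=True)
class DoseHistogram:
    """Per-voxel dose histogram ``(w_i, D_i)`` with ascending bin doses."""

    bin_doses: np.ndarray
    bin_weights: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.bin_doses, dtype=float)
        w = np.asarray(self.bin_weights, dtype=float)
        if d.ndim != 1 or w.shape != d.shape or d.size == 0:
            raise InputError("histogram bins must be 1-D, equal-length and non-empty")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(w))):
            raise InputError("histogram contains non-finite values")
        if np.any(d < 0):
            raise InputError("bin doses must be non-negative")
        if np.any(np.diff(d) < 0):
            raise InputError("bin doses must be non-decreasing")
        if np.any(w <= 0):
            raise InputError("bin weights must be positive")
        if abs(math.fsum(w.tolist()) - 1.0) > 1e-9:
            raise InputError("bin weights must sum to 1")
        object.__setattr__(self, "bin_doses", d)
        object.__setattr__(self, "bin_weights", w)

    @property
    def n_bins(self) -> int:
        return int(self.bin_doses.size)

    @classmethod
    def uniform(cls, dose: float, n_bins: int = 1) -> "DoseHistogram":
        """Histogram of a homogeneous dose."""
        w = np.full(n_bins, 1.0 / n_bins)
        w[-1] = 1.0 - math.fsum(w[:-1].tolist())
        return cls(np.full(n_bins, float(dose)), w)


def _validate_params(params: TissueParams) -> None:
    if not isinstance(params, TissueParams):
        raise InputError("params must be a TissueParams instance")


def log_survival_fraction(hist: DoseHistogram, params: TissueParams) -> float:
    """ln SF of the histogram, accumulated in log space.

    Never underflows for physically relevant doses: the exponents stay
    ~ -(alpha*D + beta*D^2), which is representable even for peak doses of
    hundreds of Gy.
    """
    _validate_params(params)
    d = hist.bin_doses
    exponents = np.log(hist.bin_weights) - params.alpha * d - params.beta * d * d
    # sum_i w_i exp(-aD-bD^2) <= 1, so the log is <= 0 up to rounding
    return min(float(logsumexp(exponents)), 0.0)


def survival_fraction(hist: DoseHistogram, params: TissueParams) -> float:
    """SF = sum_i w_i exp(-alpha D_i - beta D_i^2), in (0, 1].

    Warns with :class:`SurvivalUnderflowWarning` if the value underflows to
    exactly zero in double precision (use :func:`log_survival_fraction` for
    downstream arithmetic in that regime).
    """
    sf = math.exp(log_survival_fraction(hist, params))
    if sf == 0.0:
        warnings.warn(
            "survival fraction underflowed to 0; use log_survival_fraction",
            SurvivalUnderflowWarning,
            stacklevel=2,
        )
    return sf


def _eud_from_log_sf(log_sf: float, alpha: float, beta: float) -> float:
    if beta == 0.0:
        return -log_sf / alpha
    # Stable positive root of beta E^2 + alpha E + lnSF = 0:
    # E = q / (a + sqrt(a^2 + q)) with a = alpha/(2 beta), q = -lnSF/beta,
    # avoiding the cancellation of -a + sqrt(a^2 + q) for q << a^2.
    a = alpha / (2.0 * beta)
    q = -log_sf / beta
    if q == 0.0:
        return 0.0
    return q / (a + math.sqrt(a * a + q))


def eud_from_histogram(hist: DoseHistogram, params: TissueParams) -> float:
    """Equivalent uniform dose of a dose histogram, Gy.

    Satisfies ``min(D_i) <= EUD <= max(D_i)``; a uniform histogram returns its
    dose.  ``beta == 0`` is handled by the linear limit ``EUD = -ln(SF)/alpha``
    (the quadratic degenerates); ``TissueParams`` forbids beta = 0, so that
    branch is reachable only through direct calls with ad-hoc parameters.
    """
    return _eud_from_log_sf(log_survival_fraction(hist, params), params.alpha, params.beta)


def eud_batch(
    bin_weights: np.ndarray,
    bin_doses: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Vectorized EUD for many voxels at once.

    Parameters
    ----------
    bin_weights, bin_doses : (n_voxels, n_bins) arrays.  Rows may be padded
        with zero-weight bins (ignored).
    alpha, beta : (n_voxels,) arrays of LQM coefficients.
    """
    w = np.asarray(bin_weights, dtype=float)
    d = np.asarray(bin_doses, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
    log_sf = logsumexp(logw - alpha[:, None] * d - beta[:, None] * d * d, axis=1)
    log_sf = np.minimum(log_sf, 0.0)
    a = alpha / (2.0 * beta)
    q = -log_sf / beta
    return np.where(q > 0, q / (a + np.sqrt(a * a + q)), 0.0)


def eqd2(total_dose, fraction_dose, alpha_beta):
    """Equivalent dose in 2 Gy fractions.

    ``EQD2 = D (d + alpha/beta) / (2 Gy + alpha/beta)``.  Accepts scalars or
    arrays broadcast against each other.
    """
    D = np.asarray(total_dose, dtype=float)
    d = np.asarray(fraction_dose, dtype=float)
    ab = np.asarray(alpha_beta, dtype=float)
    if np.any(~np.isfinite(D)) or np.any(~np.isfinite(d)) or np.any(~np.isfinite(ab)):
        raise InputError("eqd2: non-finite input")
    if np.any(D < 0):
        raise InputError("eqd2: total dose must be non-negative")
    if np.any(d <= 0):
        raise InputError("eqd2: fraction dose must be positive")
    if np.any(ab <= 0):
        raise InputError("eqd2: alpha/beta must be positive")
    out = D * (d + ab) / (REFERENCE_FRACTION_DOSE_GY + ab)
    return float(out) if out.ndim == 0 else out


def eqd2_of_single_fraction_eud(eud, alpha_beta):
    """EQD2 of an EUD delivered as one single fraction (d = D = EUD)."""
    E = np.asarray(eud, dtype=float)
    ab = np.asarray(alpha_beta, dtype=float)
    if np.any(~np.isfinite(E)) or np.any(E < 0):
        raise InputError("eud must be finite and non-negative")
    if np.any(ab <= 0):
        raise InputError("alpha/beta must be positive")
    out = np.where(E > 0, E * (E + ab) / (REFERENCE_FRACTION_DOSE_GY + ab), 0.0)
    return float(out) if out.ndim == 0 else out


def resolve_tissue_params(
    voxel_labels: Iterable[str],
    registry: Mapping[str, TissueParams],
    priority: Sequence[str] | None = None,
    default: TissueParams | None = None,
) -> TissueParams:
    """Pick the LQM parameters of a voxel covered by zero or more contours.

    The highest-priority label present wins; labels absent from ``priority``
    rank below all listed ones, in registry order.  Unlabeled voxels fall back
    to ``default`` (registry entry ``"default"`` if present, else the package
    default alpha = 0.1 Gy^-1, beta = 0.05 Gy^-2).
    """
    if len(registry) == 0:
        raise ConfigError("empty tissue-parameter registry")
    if default is None:
        default = registry.get("default", DEFAULT_NORMAL_TISSUE)
    labels = set(voxel_labels)
    order = list(priority) if priority is not None else []
    order += [k for k in registry if k not in order]
    for name in order:
        if name in labels and name in registry:
            return registry[name]
    return default


def load_tissue_table(path) -> dict[str, TissueParams]:
    """Load a tissue registry from CSV with columns ``name, alpha, beta``.

    An optional ``alpha_beta`` column is used for rows where ``alpha`` or
    ``beta`` is missing; when both are present the ratio is derived from them.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ConfigError(f"cannot read tissue table {path!r}: {exc}") from exc
    required = {"name", "alpha", "beta"}
    if not required.issubset(df.columns):
        raise ConfigError(f"tissue table must have columns {sorted(required)}")
    registry: dict[str, TissueParams] = {}
    for _, row in df.iterrows():
        name = str(row["name"])
        alpha = None if pd.isna(row["alpha"]) else float(row["alpha"])
        beta = None if pd.isna(row["beta"]) else float(row["beta"])
        ratio = None
        if "alpha_beta" in df.columns and not pd.isna(row.get("alpha_beta")):
            ratio = float(row["alpha_beta"])
        if alpha is not None and beta is not None:
            registry[name] = TissueParams(name, alpha=alpha, beta=beta)
        else:
            registry[name] = TissueParams(name, alpha=alpha, beta=beta, alpha_beta=ratio)
    if not registry:
        raise ConfigError(f"tissue table {path!r} is empty")
    return registry
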