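"""Reduce subvoxel dose samples to the per-voxel 35-bin dose histogram.

Samples are sorted in increasing order and split into ``n_bins`` contiguous
groups of as-equal-as-possible size (equal-count / quantile groups, not
equal-width dose intervals — sorting first only matters for the former).
Each bin carries the group's mean dose and its exact volume fraction.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InputError
from .radiobiology import DoseHistogram

__all__ = ["DEFAULT_N_BINS", "build_histogram"]

#: Number of equal-count groups a voxel's sorted subvoxel doses are split into.
DEFAULT_N_BINS = 35


def _exact_weights(sizes: np.ndarray) -> np.ndarray:
    """Group-size fractions adjusted so the float weights sum to exactly 1."""
    total = int(sizes.sum())
    w = sizes.astype(float) / total
    if w.size > 1:
        w[-1] = 1.0 - math.fsum(w[:-1].tolist())
    else:
        w[0] = 1.0
    return w


def build_histogram(block, n_bins: int = DEFAULT_N_BINS) -> DoseHistogram:
    """Build the equal-count dose histogram of a subvoxel block.

    Parameters
    ----------
    block : SubvoxelBlock or array-like of sample doses (Gy).
    n_bins : target number of groups (default 35).

    Remainder samples (count not divisible by ``n_bins``) are distributed one
    per group starting from the lowest-dose group, and weights are the exact
    group fractions, so weight and mean conservation hold regardless of
    divisibility.  Blocks with fewer samples than ``n_bins`` degenerate to one
    bin per distinct dose value with proportional weights.
    """
    samples = np.asarray(getattr(block, "sample_doses", block), dtype=float).ravel()
    if samples.size == 0:
        raise InputError("cannot histogram an empty sample block")
    if not np.all(np.isfinite(samples)):
        raise InputError("sample doses contain non-finite values")
    if np.any(samples < 0):
        raise InputError("sample doses must be non-negative")
    if n_bins < 1:
        raise InputError("n_bins must be >= 1")

    if samples.size < n_bins:
        values, counts = np.unique(samples, return_counts=True)
        return DoseHistogram(values, _exact_weights(counts))

    s = np.sort(samples)
    groups = np.array_split(s, n_bins)  # first (lowest-dose) groups get remainders
    doses = np.array([g.mean() for g in groups])
    # means of sorted groups are non-decreasing in exact arithmetic; division
    # rounding can break that by 1 ulp for equal-valued groups of unequal size
    doses = np.maximum.accumulate(doses)
    sizes = np.array([g.size for g in groups])
    return DoseHistogram(doses, _exact_weights(sizes))
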