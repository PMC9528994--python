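"""Functional lung sub-region generation.

The perfusion map is min-max normalised over lung voxels and thresholded
(default 0.3) into high- and low-functional lung regions.  The whole-lung
(WL) region is both lungs minus GTV; the function-wise lung (FWL) is the
pair (high, low), which partitions WL exactly.

Conventions (the source protocol leaves these open):
- normalisation denominator is (max - min) over *lung* voxels, so the lung
  range is exactly [0, 1];
- a voxel whose normalised perfusion equals the threshold is HIGH (>=);
- the GTV is excluded from WL, high and low alike.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import BinaryMask, DegenerateROIError, ScalarVolume

logger = logging.getLogger("fwlomics")

DEFAULT_THRESHOLD = 0.3


class DegeneratePerfusionError(ValueError):
    """Perfusion is constant over the lung: no functional contrast."""


@dataclasses.dataclass
class RegionSet:
    """Whole-lung plus high/low functional sub-regions (GTV excluded)."""

    wl: BinaryMask
    high: BinaryMask
    low: BinaryMask
    threshold: float

    def __post_init__(self) -> None:
        if np.any(self.high.values & self.low.values):
            raise ValueError("high and low regions overlap")
        if np.any((self.high.values | self.low.values) != self.wl.values):
            raise ValueError("high + low do not partition the whole lung")


def normalize_perfusion(f: ScalarVolume, lung: BinaryMask) -> ScalarVolume:
    """Min-max normalise perfusion over lung voxels to the range [0, 1].

    Voxels outside the lung are set to 0 (they are never part of any
    functional region and are ignored downstream).
    """
    lung.require_nonempty("lung")
    inside = f.values[lung.values]
    lo, hi = float(inside.min()), float(inside.max())
    if hi <= lo:
        raise DegeneratePerfusionError("perfusion is constant over the lung")
    out = np.zeros_like(f.values)
    out[lung.values] = (inside - lo) / (hi - lo)
    return ScalarVolume(out, f.spacing, f.origin, unit="normalized")


def segment_functional_regions(
    fn: ScalarVolume,
    lung: BinaryMask,
    gtv: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
) -> RegionSet:
    """Split the lung into high (fn >= threshold) and low (fn < threshold)."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    wl = lung.values & ~gtv.values
    high = wl & (fn.values >= threshold)
    low = wl & (fn.values < threshold)
    if not high.any():
        logger.warning("empty high-functional region at threshold %.3g", threshold)
    if not low.any():
        logger.warning("empty low-functional region at threshold %.3g", threshold)
    mk = lambda v: BinaryMask(v, lung.spacing, lung.origin)
    return RegionSet(wl=mk(wl), high=mk(high), low=mk(low), threshold=threshold)


def build_region_set(
    perfusion: ScalarVolume,
    lung: BinaryMask,
    gtv: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
) -> RegionSet:
    """Normalise + segment in one call (the per-patient entry point)."""
    fn = normalize_perfusion(perfusion, lung)
    return segment_functional_regions(fn, lung, gtv, threshold)
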