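"""Fixed-bin-count gray-level discretisation."""

from __future__ import annotations

import dataclasses

import numpy as np

from ..core import BinaryMask, ScalarVolume


@dataclasses.dataclass
class DiscretizedROI:
    """ROI voxels mapped to integer gray levels 1..n_bins.

    levels : 3D int array over the ROI bounding box; 0 outside the mask
    mask : boolean array over the same bounding box
    n_bins : requested bin count (levels actually present may be fewer)
    bin_edges : the equal-width edges used
    raw : the undiscretised ROI voxel values (1D)
    spacing : voxel spacing of the parent volume
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    raw: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def roi_levels(self) -> np.ndarray:
        """Gray levels of ROI voxels only (1D)."""
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _bounding_box(mask: np.ndarray) -> tuple[slice, ...]:
    idx = np.nonzero(mask)
    return tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)


def discretize_fixed_bin_count(
    v: ScalarVolume, roi: BinaryMask, n_bins: int
) -> DiscretizedROI:
    """Equal-width bins spanning [min, max] of ROI voxels.

    The maximum value is assigned to bin ``n_bins`` (closed top bin); a
    constant ROI maps every voxel to level 1.
    """
    roi.require_nonempty()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bb = _bounding_box(roi.values)
    mask = roi.values[bb]
    vals = v.values[bb]
    raw = vals[mask]
    lo, hi = float(raw.min()), float(raw.max())
    levels = np.zeros(mask.shape, dtype=np.int64)
    if hi <= lo:
        levels[mask] = 1
        edges = np.array([lo, lo])
    else:
        width = (hi - lo) / n_bins
        lv = np.floor((vals - lo) / width).astype(np.int64) + 1
        np.clip(lv, 1, n_bins, out=lv)
        levels[mask] = lv[mask]
        edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedROI(
        levels=levels,
        mask=mask,
        n_bins=n_bins,
        bin_edges=edges,
        raw=raw,
        spacing=v.spacing,
    )
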