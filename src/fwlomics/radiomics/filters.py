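"""Image filter bank: wavelet sub-bands, Laplacian-of-Gaussian, square, sqrt.

All filters operate on the full volume (before ROI masking) so texture at
the ROI boundary sees real context.  Square and square-root act on
intensities shifted to be non-negative (min-shift over the volume).
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy import ndimage

from ..core import ScalarVolume
from .settings import ExtractionSettings

logger = logging.getLogger("fwlomics")

_WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _swt_subbands(values: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """Level-1 stationary (undecimated) 3D wavelet sub-bands.

    pywt.swtn needs even-sized axes; odd axes are reflect-padded then cropped.
    pywt names detail keys with 'a'/'d' per axis, e.g. 'ada'.
    """
    pad = [(0, s % 2) for s in values.shape]
    padded = np.pad(values, pad, mode="reflect") if any(p[1] for p in pad) else values
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    out = {}
    for band in _WAVELET_BANDS:
        key = "".join("a" if c == "L" else "d" for c in band)
        arr = coeffs[key]
        out[f"wavelet-{band}"] = arr[tuple(slice(0, s) for s in values.shape)]
    return out


def apply_filter_bank(
    v: ScalarVolume, settings: ExtractionSettings | None = None
) -> dict[str, ScalarVolume]:
    """Return the requested image types as a name -> ScalarVolume map."""
    settings = settings or ExtractionSettings()
    vals = v.values
    out: dict[str, np.ndarray] = {}
    wanted = set(settings.image_types)
    if "original" in wanted:
        out["original"] = vals
    if any(t.startswith("wavelet") for t in wanted):
        for name, arr in _swt_subbands(vals, settings.wavelet).items():
            if name in wanted:
                out[name] = arr
    if "log-sigma-1" in wanted:
        out["log-sigma-1"] = ndimage.gaussian_laplace(
            vals, sigma=settings.log_sigma_voxels, mode="reflect"
        )
    if "square" in wanted or "squareroot" in wanted:
        shifted = vals - vals.min()
        if "square" in wanted:
            out["square"] = shifted**2
        if "squareroot" in wanted:
            out["squareroot"] = np.sqrt(shifted)
    ordered = {t: out[t] for t in settings.image_types}
    return {
        name: ScalarVolume(arr, v.spacing, v.origin, unit="normalized")
        for name, arr in ordered.items()
    }
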