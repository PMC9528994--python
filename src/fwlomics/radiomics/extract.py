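"""Catalog extraction: image types x bin counts x feature classes."""

from __future__ import annotations

import logging

from ..core import BinaryMask, ScalarVolume
from .discretize import discretize_fixed_bin_count
from .filters import apply_filter_bank
from .firstorder import first_order_features
from .settings import ExtractionSettings
from .shape import shape_features
from .texture import TEXTURE_FAMILIES, texture_features

logger = logging.getLogger("fwlomics")


def extract_intensity_features(
    image: ScalarVolume, roi: BinaryMask, n_bins: int
) -> dict[str, float]:
    """The 91 intensity features (first-order + 5 texture families) for one
    image at one bin count.  Keys are '<class>:<Feature>'."""
    d = discretize_fixed_bin_count(image, roi, n_bins)
    out = {f"firstorder:{k}": v for k, v in first_order_features(d).items()}
    for family in TEXTURE_FAMILIES:
        for k, v in texture_features(d, family).items():
            out[f"{family}:{k}"] = v
    return out


def extract_radiomics_catalog(
    v: ScalarVolume, roi: BinaryMask, settings: ExtractionSettings | None = None
) -> dict[str, float]:
    """Full radiomics vector for one ROI.

    Keys: '<image type>:bin<N>:<class>:<Feature>' for intensity features
    and 'original:shape:<Feature>' for shape; the default settings yield
    exactly 5,474 values.
    """
    settings = settings or ExtractionSettings()
    roi.require_nonempty()
    images = apply_filter_bank(v, settings)
    out: dict[str, float] = {}
    for itype, img in images.items():
        for nb in settings.bin_counts:
            feats = extract_intensity_features(img, roi, nb)
            for k, val in feats.items():
                out[f"{itype}:bin{nb}:{k}"] = val
    if settings.include_shape:
        for k, val in shape_features(roi).items():
            out[f"original:shape:{k}"] = val
    logger.debug("radiomics catalog: %d features on %d voxels", len(out), roi.count)
    assert len(out) == settings.catalog_size
    return out
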