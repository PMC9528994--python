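"""Extraction settings and catalog arithmetic."""

from __future__ import annotations

import dataclasses

# Intensity feature classes and their sizes (the standard reference split).
FEATURE_CLASS_SIZES = {
    "firstorder": 18,
    "glcm": 22,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}
INTENSITY_FEATURE_COUNT = sum(FEATURE_CLASS_SIZES.values())  # 91
SHAPE_FEATURE_COUNT = 14

# original + 8 stationary-wavelet sub-bands + LoG + square + square-root
DEFAULT_IMAGE_TYPES = (
    "original",
    "wavelet-LLL", "wavelet-LLH", "wavelet-LHL", "wavelet-LHH",
    "wavelet-HLL", "wavelet-HLH", "wavelet-HHL", "wavelet-HHH",
    "log-sigma-1", "square", "squareroot",
)
DEFAULT_BIN_COUNTS = (20, 50, 100, 150, 200)


@dataclasses.dataclass(frozen=True)
class ExtractionSettings:
    """Which images, discretisations and feature classes to extract.

    The default reproduces the full catalog:
    |image_types| * |bin_counts| * 91 + 14 shape = 12 * 5 * 91 + 14 = 5,474.
    """

    image_types: tuple[str, ...] = DEFAULT_IMAGE_TYPES
    bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS
    include_shape: bool = True
    wavelet: str = "coif1"
    log_sigma_voxels: float = 1.0

    def __post_init__(self) -> None:
        if any(b < 2 for b in self.bin_counts):
            raise ValueError("bin counts must be >= 2")
        unknown = set(self.image_types) - set(DEFAULT_IMAGE_TYPES)
        if unknown:
            raise ValueError(f"unknown image types: {sorted(unknown)}")

    @property
    def catalog_size(self) -> int:
        n = len(self.image_types) * len(self.bin_counts) * INTENSITY_FEATURE_COUNT
        if self.include_shape:
            n += SHAPE_FEATURE_COUNT
        return n


#: Reduced settings used for cohort-scale experiments (desk scale).
REDUCED_SETTINGS = ExtractionSettings(
    image_types=("original",), bin_counts=(50,), include_shape=True
)
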