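"""First-order intensity statistics (18 features).

Statistics are computed from the raw ROI intensities; Entropy and
Uniformity use the discretised gray-level histogram.  Definitions follow
the standard reference-implementation formulas: population variance,
Fisher-Pearson skewness, non-excess kurtosis, entropy in bits.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(d: DiscretizedROI) -> dict[str, float]:
    x = d.raw
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    counts = np.bincount(d.roi_levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    skew = float(((x - mean) ** 3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float(((x - mean) ** 4).mean() / var**2) if var > 0 else 0.0

    energy = float((x**2).sum())
    voxvol = float(np.prod(d.spacing))
    return {
        "Energy": energy,
        "TotalEnergy": voxvol * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
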